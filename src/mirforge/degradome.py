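"""Degradome (PARE) target validation: 5'-end tag gating, per-transcript
T-plots, miRNA:target complementarity scoring, and cleavage-site
categorization.

Degradome reads are gated on a diagnostic 5' adaptor (``CAGCAG``), trimmed
to fixed-length 5'-end tags, and mapped exactly to transcripts; the 5'-most
coordinate of each mapped tag increments the transcript's T-plot.  A miRNA
slid over a transcript in antisense orientation yields candidate sites
wherever the complementarity penalty is at or below the cutoff and degradome
signal occupies the predicted slicing position (the transcript base paired
to miRNA position 10).  Sites are classified 0-4 by peak height relative to
the transcript maximum and the median over occupied positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = [
    "DegradomeTag",
    "TPlot",
    "TargetSite",
    "gate_and_trim",
    "build_tplots",
    "score_alignment",
    "find_sites",
    "categorize",
    "render_tplot",
]

#: positions (1-based from the miRNA 5' end) where penalties are doubled
CORE_START, CORE_END = 2, 13
MISMATCH_PENALTY = 1.0
GU_PENALTY = 0.5
#: miRNA position whose paired transcript base is reported as the cleavage site
CLEAVAGE_REGISTER = 10


@dataclass(frozen=True)
class DegradomeTag:
    sequence: str
    count: int


@dataclass
class TPlot:
    """Per-transcript profile of degradome 5'-end counts (1-based)."""

    transcript: str
    length: int
    profile: dict[int, int]

    def occupied(self) -> list[int]:
        return sorted(self.profile)

    def max_count(self) -> int:
        return max(self.profile.values(), default=0)

    def median_occupied(self) -> float:
        vals = sorted(self.profile.values())
        if not vals:
            return 0.0
        n = len(vals)
        mid = n // 2
        return float(vals[mid]) if n % 2 else (vals[mid - 1] + vals[mid]) / 2.0


@dataclass
class TargetSite:
    mirna: str
    transcript: str
    alignment: str
    score: float
    cleavage_position: int  # 1-based transcript coordinate
    category: int
    peak_count: int
    transcript_max: int
    transcript_median: float


def gate_and_trim(
    reads: list[str], adaptor: str = "CAGCAG", tag_len: int = 20, min_len: int = 15
) -> list[DegradomeTag]:
    """Keep reads starting with the 5' adaptor; trim to the first
    ``tag_len`` nt of the insert; collapse duplicates with counts."""
    counts: Counter[str] = Counter()
    for read in reads:
        read = read.upper()
        if not read.startswith(adaptor.upper()):
            continue
        tag = read[len(adaptor) : len(adaptor) + tag_len]
        if len(tag) >= min_len:
            counts[tag] += 1
    tags = [DegradomeTag(s, c) for s, c in counts.items()]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags


def build_tplots(
    tags: list[DegradomeTag], transcripts: dict[str, str]
) -> dict[str, TPlot]:
    """Exact sense-strand matching of tags into per-transcript profiles.

    Each tag increments the 5'-most matching coordinate of every transcript
    it matches (multi-transcript hits count on each).
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    plots = {
        name: TPlot(name, len(seq), {}) for name, seq in transcripts.items()
    }
    upper = {name: seq.upper() for name, seq in transcripts.items()}
    for tag in tags:
        for name, seq in upper.items():
            k = seq.find(tag.sequence)
            if k >= 0:
                pos = k + 1
                plots[name].profile[pos] = plots[name].profile.get(pos, 0) + tag.count
    return plots


def _pair_kind(mirna_base: str, target_base: str) -> str:
    """``wc`` / ``gu`` / ``mm`` for a miRNA base opposite a target base."""
    a, b = mirna_base, target_base
    if (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}:
        return "wc"
    if (a, b) in {("G", "U"), ("U", "G")}:
        return "gu"
    return "mm"


def score_alignment(mirna: str, window: str) -> tuple[float, str]:
    """Complementarity penalty of a miRNA against an equal-length target
    window (both 5'->3', RNA).

    Penalties per miRNA position (1-based from its 5' end): mismatch 1.0,
    G:U wobble 0.5, doubled within positions 2-13.  The alignment string is
    reported 5'->3' along the *miRNA*: ``|`` Watson-Crick, ``o`` G:U,
    ``.`` mismatch.
    """
    m = mirna.upper().replace("T", "U")
    w = window.upper().replace("T", "U")
    if len(m) != len(w):
        raise ValueError("gapless mode requires window length == miRNA length")
    score = 0.0
    marks = []
    L = len(m)
    for i in range(1, L + 1):
        kind = _pair_kind(m[i - 1], w[L - i])
        pen = {"wc": 0.0, "gu": GU_PENALTY, "mm": MISMATCH_PENALTY}[kind]
        if CORE_START <= i <= CORE_END:
            pen *= 2
        score += pen
        marks.append({"wc": "|", "gu": "o", "mm": "."}[kind])
    return score, "".join(marks)


def find_sites(
    mirna_name: str,
    mirna_seq: str,
    transcript_name: str,
    transcript_seq: str,
    tplot: TPlot,
    score_cutoff: float = 7.0,
) -> list[TargetSite]:
    """Slide the miRNA over a transcript and report supported cleavage sites.

    A window is a site when its penalty is <= ``score_cutoff`` and the
    T-plot is occupied at the predicted cleavage coordinate (the transcript
    base paired to miRNA position ``CLEAVAGE_REGISTER``).
    """
    m = mirna_seq.upper().replace("T", "U")
    t = transcript_seq.upper().replace("T", "U")
    L = len(m)
    sites = []
    for s in range(0, len(t) - L + 1):
        window = t[s : s + L]
        score, aln = score_alignment(m, window)
        if score > score_cutoff:
            continue
        # miRNA position i pairs transcript position s + (L - i) (0-based)
        cleav = s + (L - CLEAVAGE_REGISTER) + 1  # 1-based
        c = tplot.profile.get(cleav, 0)
        if c < 1:
            continue
        cat = categorize(cleav, tplot)
        sites.append(
            TargetSite(
                mirna=mirna_name,
                transcript=transcript_name,
                alignment=aln,
                score=score,
                cleavage_position=cleav,
                category=cat,
                peak_count=c,
                transcript_max=tplot.max_count(),
                transcript_median=tplot.median_occupied(),
            )
        )
    return sites


def categorize(position: int, tplot: TPlot) -> int:
    """Category of an occupied cleavage position.

    With ``c`` the count at the position, ``M`` the transcript maximum and
    ``med`` the median over occupied positions: 4 if c == 1; else 0 if c is
    the unique maximum; 1 if c equals a shared maximum; 2 if med < c < M;
    3 if c <= med.
    """
    c = tplot.profile.get(position, 0)
    if c < 1:
        raise ValueError(f"position {position} unoccupied in {tplot.transcript}")
    if c == 1:
        return 4
    M = tplot.max_count()
    med = tplot.median_occupied()
    if c == M:
        n_at_max = sum(1 for v in tplot.profile.values() if v == M)
        return 0 if n_at_max == 1 else 1
    if c > med:
        return 2
    return 3


def render_tplot(tplot: TPlot, site: TargetSite | None = None, path=None):
    """Line plot of degradome counts versus transcript position, with the
    cleavage site highlighted.  Deterministic for fixed input."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # content-derived hash salt keeps SVG element ids reproducible
    plt.rcParams["svg.hashsalt"] = "mirforge"
    fig, ax = plt.subplots(figsize=(6, 3))
    xs = list(range(1, tplot.length + 1))
    ys = [tplot.profile.get(x, 0) for x in xs]
    ax.plot(xs, ys, lw=0.8, color="0.3")
    if site is not None:
        ax.axvline(site.cleavage_position, color="red", lw=1.0)
        ax.plot(
            [site.cleavage_position],
            [tplot.profile.get(site.cleavage_position, 0)],
            "rv",
        )
    ax.set_xlabel(f"{tplot.transcript} position (nt)")
    ax.set_ylabel("degradome 5'-end count")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else {})
        plt.close(fig)
        return path
    return fig
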