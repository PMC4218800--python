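"""Known-miRNA mapping and novel-miRNA hairpin validation.

Known miRNAs are called by aligning clean unique tags to reference mature
sequences, allowing length variation at both ends plus at most one internal
substitution, and naming the result with the end-offset convention
(``base_L-4_R+1_1ss13GA``).  Tags that match no reference are mapped to the
genome, 120-nt flanking windows are folded, and the resulting hairpins are
screened by eleven explicit structural criteria (stem pairing, bulge sizes,
free energy, loop geometry, and pairing of the mature region) before a locus
is accepted as a novel miRNA precursor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .fold import fold, pair_table

__all__ = [
    "MiRNAVariantName",
    "HairpinCandidate",
    "CriteriaMetrics",
    "CriteriaThresholds",
    "CRITERION_ORDER",
    "format_variant_name",
    "parse_variant_name",
    "map_to_matures",
    "extract_flanks",
    "compute_metrics",
    "passes_criteria",
    "evaluate_window",
    "classify_arm",
    "assign_family",
    "revcomp",
]

_COMP = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# variant naming


@dataclass(frozen=True)
class MiRNAVariantName:
    """A mature-miRNA variant: reference name, signed end offsets, and at
    most one internal substitution (1-based position on the tag, reference
    base, observed base)."""

    base: str
    left_offset: int = 0
    right_offset: int = 0
    substitution: tuple[int, str, str] | None = None


def format_variant_name(v: MiRNAVariantName) -> str:
    parts = [v.base]
    if v.left_offset:
        parts.append(f"L{v.left_offset:+d}")
    if v.right_offset:
        parts.append(f"R{v.right_offset:+d}")
    if v.substitution is not None:
        pos, ref, obs = v.substitution
        parts.append(f"1ss{pos}{ref}{obs}")
    return "_".join(parts)


_L_RE = re.compile(r"^L([+-]\d+)$")
_R_RE = re.compile(r"^R([+-]\d+)$")
_SS_RE = re.compile(r"^1ss(\d+)([ACGTU])([ACGTU])$")


def parse_variant_name(s: str) -> MiRNAVariantName:
    """Inverse of :func:`format_variant_name`.

    Suffix segments are recognised from the right so that underscores inside
    the base name (e.g. novel ``PC-3p-115345_10``) are preserved.
    """
    tokens = s.split("_")
    sub: tuple[int, str, str] | None = None
    left = right = 0
    # consume, right to left, in the fixed order ss -> R -> L
    if tokens and (m := _SS_RE.match(tokens[-1])):
        sub = (int(m.group(1)), m.group(2), m.group(3))
        tokens.pop()
    elif tokens and tokens[-1].startswith("1ss"):
        raise ValueError(f"malformed substitution segment {tokens[-1]!r} in {s!r}")
    if tokens and (m := _R_RE.match(tokens[-1])):
        right = int(m.group(1))
        tokens.pop()
    if tokens and (m := _L_RE.match(tokens[-1])):
        left = int(m.group(1))
        tokens.pop()
    if not tokens or not tokens[0]:
        raise ValueError(f"missing base name in {s!r}")
    for t in tokens[1:]:
        if _L_RE.match(t) or _R_RE.match(t) or t.startswith("1ss"):
            raise ValueError(f"variant segment {t!r} out of order in {s!r}")
    return MiRNAVariantName("_".join(tokens), left, right, sub)


# both names used in combined L/R segments like "L-1R+1" (seen in curated
# target tables); normalise those on parse as a convenience
_LR_RE = re.compile(r"^L([+-]\d+)R([+-]\d+)$")


def parse_variant_name_lenient(s: str) -> MiRNAVariantName:
    """Like :func:`parse_variant_name` but also accepts the fused form
    ``base_L-1R+1_...`` used in some published tables."""
    tokens = s.split("_")
    for k, t in enumerate(tokens):
        if m := _LR_RE.match(t):
            tokens[k : k + 1] = [f"L{m.group(1)}", f"R{m.group(2)}"]
            return parse_variant_name("_".join(tokens))
    return parse_variant_name(s)


# ---------------------------------------------------------------------------
# mapping tags to reference matures


def map_to_matures(
    tag: str,
    matures: dict[str, str],
    precursors: dict[str, str] | None = None,
    max_end_shift: int = 4,
    max_internal_mismatch: int = 1,
) -> list[MiRNAVariantName]:
    """All reference matures reachable from ``tag`` by end variation and at
    most one internal substitution.

    End extensions (positive offsets) are validated against the precursor
    sequence when one is supplied for the reference; without precursor
    context only trims and exact-length matches are possible.  Results are
    sorted best-first (fewest substitutions, then smallest total end shift).
    """
    tag = tag.upper().replace("U", "T")
    hits: list[tuple[tuple[int, int], MiRNAVariantName]] = []
    for name, mat in matures.items():
        mat = mat.upper().replace("U", "T")
        prec = None
        off = -1
        if precursors and name in precursors:
            prec = precursors[name].upper().replace("U", "T")
            off = prec.find(mat)
            if off < 0:
                prec = None
        dtot = len(tag) - len(mat)
        for dl in range(-max_end_shift, max_end_shift + 1):
            dr = dtot - dl
            if abs(dr) > max_end_shift:
                continue
            cand = _shift_ends(mat, prec, off, dl, dr)
            if cand is None:
                continue
            mism = [k for k in range(len(tag)) if tag[k] != cand[k]]
            if len(mism) > max_internal_mismatch:
                continue
            sub = None
            if mism:
                p = mism[0]
                sub = (p + 1, cand[p], tag[p])
            hits.append(
                ((len(mism), abs(dl) + abs(dr)), MiRNAVariantName(name, dl, dr, sub))
            )
    hits.sort(key=lambda h: (h[0], h[1].base))
    return [v for _, v in hits]


def _shift_ends(
    mat: str, prec: str | None, off: int, dl: int, dr: int
) -> str | None:
    """Apply signed end offsets to a mature; extensions need the precursor."""
    s = mat
    if dl < 0:
        if -dl >= len(s):
            return None
        s = s[-dl:]
    elif dl > 0:
        if prec is None or off - dl < 0:
            return None
        s = prec[off - dl : off] + s
    if dr < 0:
        if -dr >= len(s):
            return None
        s = s[:dr]
    elif dr > 0:
        if prec is None or off < 0 or off + len(mat) + dr > len(prec):
            return None
        s = s + prec[off + len(mat) : off + len(mat) + dr]
    return s if s else None


# ---------------------------------------------------------------------------
# hairpin candidates and the 11-criterion screen


@dataclass
class HairpinCandidate:
    """A folded precursor window anchored on a candidate mature tag."""

    contig: str
    start: int  # 1-based inclusive, on the forward strand of the contig
    end: int
    strand: str  # "+" or "-"
    sequence: str  # RNA, window orientation (reverse-complemented for "-")
    structure: str
    free_energy: float
    mature_span: tuple[int, int]  # 0-based inclusive within sequence
    arm: str = "?"  # 5p / 3p / loop / none


@dataclass(frozen=True)
class CriteriaMetrics:
    max_stem_bulge_nt: int
    stem_base_pairs: int
    free_energy_kcal: float
    hairpin_length_nt: int
    loop_length_nt: int
    max_mature_bulge_nt: int
    mature_biased_errors_in_one_bulge: int
    mature_biased_bulges: int
    mature_errors: int
    mature_base_pairs: int
    mature_pct_in_stem: float
    arm: str = "none"


@dataclass(frozen=True)
class CriteriaThresholds:
    """Structural acceptance thresholds for novel precursors.

    ``max_free_energy_kcal`` is the upper bound on the folding free energy:
    candidates must be at least this stable (dG <= -15 kcal/mol by default).
    """

    max_stem_bulge_nt: int = 12
    min_stem_base_pairs: int = 16
    max_free_energy_kcal: float = -15.0
    min_hairpin_length_nt: int = 50
    max_loop_length_nt: int = 200
    max_mature_bulge_nt: int = 4
    max_mature_biased_errors_in_one_bulge: int = 2
    max_mature_biased_bulges: int = 2
    max_mature_errors: int = 4
    min_mature_base_pairs: int = 12
    min_mature_pct_in_stem: float = 80.0


#: criterion keys in report order
CRITERION_ORDER = (
    "stem_bulge",
    "stem_pairs",
    "free_energy",
    "hairpin_length",
    "loop_length",
    "mature_bulge",
    "mature_biased_errors",
    "mature_biased_bulges",
    "mature_errors",
    "mature_pairs",
    "mature_pct_in_stem",
)


def _hairpin_loops(pt: dict[int, int]) -> list[tuple[int, int]]:
    loops = []
    for i, j in pt.items():
        if i < j and not any(i < k < j for k in pt if i < k < pt[k] < j):
            loops.append((i, j))
    return sorted(loops)


def _stem_chain(pt: dict[int, int], loop: tuple[int, int]) -> list[tuple[int, int]]:
    """Walk outward from a hairpin-closing pair while the enclosing pair
    directly encloses only this helix (stop at multiloops)."""
    chain = [loop]
    while True:
        i, j = chain[-1]
        parents = [
            (a, pt[a]) for a in pt if a < i and pt[a] > j and a < pt[a]
        ]
        if not parents:
            break
        a, b = max(parents)  # nearest enclosing pair
        # any other paired nucleotide strictly between (a, b) but outside
        # (i, j) means (a, b) closes a multiloop, not this stem
        branch = any(
            a < k < i or j < k < b for k in pt if not (i <= k <= j) and k != a and k != b
        )
        if branch:
            break
        chain.append((a, b))
    return chain[::-1]  # outermost first


def compute_metrics(c: HairpinCandidate) -> CriteriaMetrics:
    """Measure the 11 structural quantities of the candidate hairpin.

    The stem is the helix chain closing the terminal loop nearest the mature
    span; internal loops between consecutive stem pairs contribute bulge and
    error counts.  Within an internal loop with ``gm`` unpaired nucleotides
    on the mature arm (restricted to the mature span) and ``go`` on the
    opposite arm, ``min(gm, go)`` are *errors* (opposed mismatches) and a
    loop with ``gm > go`` is a mature-*biased bulge* of ``gm`` nucleotides.
    """
    pt = pair_table(c.structure)
    ms, me = c.mature_span
    zero = CriteriaMetrics(0, 0, c.free_energy, 0, 0, 0, 0, 0, 0, 0, 0.0)
    if not pt:
        return zero
    loops = _hairpin_loops(pt)
    if not loops:
        return zero
    # choose the hairpin whose stem span overlaps the mature most; ties by
    # larger stem
    best = None
    for lp in loops:
        chain = _stem_chain(pt, lp)
        a0, b0 = chain[0]
        ov = max(0, min(me, b0) - max(ms, a0) + 1)
        key = (ov, len(chain), -a0)
        if best is None or key > best[0]:
            best = (key, chain)
    chain = best[1]
    (a0, b0), (ik, jk) = chain[0], chain[-1]
    loop_len = jk - ik - 1
    stem_bp = len(chain)
    hairpin_len = b0 - a0 + 1

    mature_len = me - ms + 1
    # arm of the mature relative to the terminal loop
    mid = (ms + me) / 2
    if mid < ik:
        arm = "5p"
    elif mid > jk:
        arm = "3p"
    else:
        arm = "loop"

    max_stem_bulge = 0
    mat_errors = 0
    mat_biased_bulges = 0
    max_mat_bulge = 0
    mat_biased_err = 0
    for (a, b), (cc, d) in zip(chain, chain[1:]):
        g5, g3 = cc - a - 1, b - d - 1
        max_stem_bulge = max(max_stem_bulge, g5, g3)
        if arm == "5p":
            gm = _overlap(a + 1, cc - 1, ms, me)
            go = g3
        elif arm == "3p":
            gm = _overlap(d + 1, b - 1, ms, me)
            go = g5
        else:
            continue
        if gm == 0:
            continue
        mat_errors += min(gm, go)
        if gm > go:
            mat_biased_bulges += 1
            max_mat_bulge = max(max_mat_bulge, gm)
            mat_biased_err = max(mat_biased_err, min(gm, go))

    mature_bp = sum(1 for p in range(ms, me + 1) if p in pt)
    in_stem = sum(
        1 for p in range(ms, me + 1) if a0 <= p <= ik or jk <= p <= b0
    )
    pct = 100.0 * in_stem / mature_len if mature_len else 0.0
    return CriteriaMetrics(
        max_stem_bulge_nt=max_stem_bulge,
        stem_base_pairs=stem_bp,
        free_energy_kcal=c.free_energy,
        hairpin_length_nt=hairpin_len,
        loop_length_nt=loop_len,
        max_mature_bulge_nt=max_mat_bulge,
        mature_biased_errors_in_one_bulge=mat_biased_err,
        mature_biased_bulges=mat_biased_bulges,
        mature_errors=mat_errors,
        mature_base_pairs=mature_bp,
        mature_pct_in_stem=round(pct, 1),
        arm=arm,
    )


def _overlap(lo: int, hi: int, ms: int, me: int) -> int:
    return max(0, min(hi, me) - max(lo, ms) + 1)


def passes_criteria(
    m: CriteriaMetrics, thresholds: CriteriaThresholds | None = None
) -> tuple[bool, dict[str, bool]]:
    """Per-criterion verdicts and the overall pass (all 11 must hold)."""
    t = thresholds or CriteriaThresholds()
    v = {
        "stem_bulge": m.max_stem_bulge_nt <= t.max_stem_bulge_nt,
        "stem_pairs": m.stem_base_pairs >= t.min_stem_base_pairs,
        "free_energy": m.free_energy_kcal <= t.max_free_energy_kcal,
        "hairpin_length": m.hairpin_length_nt >= t.min_hairpin_length_nt,
        "loop_length": m.loop_length_nt <= t.max_loop_length_nt,
        "mature_bulge": m.max_mature_bulge_nt <= t.max_mature_bulge_nt,
        "mature_biased_errors": m.mature_biased_errors_in_one_bulge
        <= t.max_mature_biased_errors_in_one_bulge,
        "mature_biased_bulges": m.mature_biased_bulges <= t.max_mature_biased_bulges,
        "mature_errors": m.mature_errors <= t.max_mature_errors,
        "mature_pairs": m.mature_base_pairs >= t.min_mature_base_pairs,
        "mature_pct_in_stem": m.mature_pct_in_stem >= t.min_mature_pct_in_stem,
    }
    return all(v.values()), v


# ---------------------------------------------------------------------------
# genomic flank extraction and window evaluation


@dataclass(frozen=True)
class FlankWindow:
    contig: str
    start: int  # 1-based inclusive forward-strand coordinates
    end: int
    strand: str
    sequence: str  # window orientation (revcomp for minus strand), DNA
    tag_offset: int  # 0-based offset of the tag within `sequence`
    tag_length: int
    side: str  # "downstream" (tag+flank) or "upstream" (flank+tag)


def _find_all(hay: str, needle: str) -> list[int]:
    out, k = [], hay.find(needle)
    while k >= 0:
        out.append(k)
        k = hay.find(needle, k + 1)
    return out


def extract_flanks(
    genome: dict[str, str],
    tag: str,
    flank: int = 120,
    max_loci: int = 20,
) -> list[FlankWindow]:
    """Candidate precursor windows for a tag: tag + ``flank`` nt downstream,
    and ``flank`` nt upstream + tag, for every exact genomic hit on either
    strand (clipped at contig ends).  Tags hitting more than ``max_loci``
    loci are treated as repetitive and yield no windows."""
    tag = tag.upper().replace("U", "T")
    L = len(tag)
    hits: list[tuple[str, int, str]] = []
    for contig, seq in genome.items():
        seq = seq.upper()
        for p in _find_all(seq, tag):
            hits.append((contig, p, "+"))
        for p in _find_all(seq, revcomp(tag)):
            hits.append((contig, p, "-"))
    if len(hits) > max_loci:
        return []
    windows = []
    for contig, p, strand in hits:
        seq = genome[contig].upper()
        n = len(seq)
        if strand == "+":
            spans = [
                (p, min(n, p + L + flank), 0, "downstream"),
                (max(0, p - flank), p + L, p - max(0, p - flank), "upstream"),
            ]
            for lo, hi, toff, side in spans:
                windows.append(
                    FlankWindow(contig, lo + 1, hi, "+", seq[lo:hi], toff, L, side)
                )
        else:
            # on the minus strand "downstream of the tag" is upstream in
            # forward coordinates; windows are reverse-complemented
            spans = [
                (max(0, p - flank), p + L, "downstream"),
                (p, min(n, p + L + flank), "upstream"),
            ]
            for lo, hi, side in spans:
                w = revcomp(seq[lo:hi])
                toff = (hi - (p + L)) if side == "downstream" else (hi - (p + L))
                windows.append(
                    FlankWindow(contig, lo + 1, hi, "-", w, toff, L, side)
                )
    return windows


def evaluate_window(
    w: FlankWindow, thresholds: CriteriaThresholds | None = None
) -> tuple[HairpinCandidate, CriteriaMetrics, bool, dict[str, bool]]:
    """Fold a flank window and screen it against the 11 criteria."""
    structure, energy = fold(w.sequence)
    cand = HairpinCandidate(
        contig=w.contig,
        start=w.start,
        end=w.end,
        strand=w.strand,
        sequence=w.sequence.replace("T", "U"),
        structure=structure,
        free_energy=energy,
        mature_span=(w.tag_offset, w.tag_offset + w.tag_length - 1),
    )
    m = compute_metrics(cand)
    cand.arm = m.arm
    ok, verdicts = passes_criteria(m, thresholds)
    return cand, m, ok, verdicts


def classify_arm(
    tag_span: tuple[int, int],
    precursor_structure: str,
    annotated_mature_span: tuple[int, int],
) -> str:
    """Place a tag on a known precursor relative to its annotated mature.

    Returns ``known`` (same arm as the annotated mature), ``novel_5p`` /
    ``novel_3p`` (entirely on the opposite arm), or ``loop`` (overlapping the
    terminal loop; excluded from calling).
    """
    pt = pair_table(precursor_structure)
    loops = _hairpin_loops(pt)
    if not loops:
        return "loop"
    ms, me = annotated_mature_span
    best = None
    for lp in loops:
        chain = _stem_chain(pt, lp)
        a0, b0 = chain[0]
        ov = max(0, min(me, b0) - max(ms, a0) + 1)
        if best is None or (ov, len(chain)) > best[0]:
            best = ((ov, len(chain)), chain)
    chain = best[1]
    ik, jk = chain[-1]

    def arm_of(lo: int, hi: int) -> str:
        if hi < ik:
            return "5p"
        if lo > jk:
            return "3p"
        return "loop"

    mat_arm = arm_of(ms, me)
    tag_arm = arm_of(*tag_span)
    if tag_arm == "loop":
        return "loop"
    if tag_arm == mat_arm:
        return "known"
    return f"novel_{tag_arm}"


_FAMILY_RE = re.compile(r"miR(\d+)", re.IGNORECASE)


def assign_family(name: str) -> str | None:
    """Reduce a miRNA name to its family (``ppt-miR166m_R-3`` -> ``miR166``).

    Novel placeholder names (``PC-...``) have no family.
    """
    if name.startswith("PC-"):
        return None
    m = _FAMILY_RE.search(name)
    return f"miR{m.group(1)}" if m else None
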