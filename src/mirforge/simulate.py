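"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates a four-tissue plant small-RNA experiment: per-tissue
FASTQ libraries containing planted known and novel miRNAs at configurable
abundance plus adapter-less, low-complexity and contaminant background;
genomic contigs whose flanks fold into criteria-passing hairpins at the
planted novel loci; a degradome library with enriched 5' ends at planted
cleavage positions; and comparative-Ct qPCR tables with known fold changes.

Planted reads are constructed to be unambiguous under the pipeline's own
rules: miRNA inserts are rejection-sampled until they pass the junk screen
and match no contaminant, junk inserts are built to trigger one named rule,
and precursors are verified at construction time to fold into exactly the
intended structure under the package folding engine (which the hairpin
criteria contract explicitly permits).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .degradome import TPlot, categorize
from .fold import fold
from .identify import (
    CriteriaThresholds,
    HairpinCandidate,
    compute_metrics,
    map_to_matures,
    passes_criteria,
    revcomp,
)
from .preprocess import is_junk, trim_adapter

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_precursor",
    "build_criterion_suite",
    "build_ground_truth",
    "simulate_srna_libraries",
    "simulate_degradome",
    "simulate_qpcr",
    "simulate_all",
]

#: bases appended after the 3' adapter so every raw read reaches 36 nt
ADAPTER_FILLER = "TCGTATGCCGTCTTCTGCTTG"
READ_LEN = 36
TISSUES = ("root", "stem", "leaf", "flower")


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults describe a small four-tissue design: 30 known and 6 novel
    miRNAs, 10,000 reads per library, 30% tissue-exclusive miRNAs, and a
    background mix of RNA-family/repeat contaminants, junk and adapter-less
    reads totalling about a third of each library.
    """

    seed: int = 0
    n_tissues: int = 4
    n_known_mirnas: int = 30
    n_novel_loci: int = 6
    n_background_loci: int = 6
    library_depth: int = 10_000
    tissue_exclusive_fraction: float = 0.3
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.10,
            "tRNA": 0.03,
            "snoRNA": 0.01,
            "snRNA": 0.01,
            "other_Rfam": 0.02,
            "repeat": 0.02,
            "junk": 0.02,
            "no_adapter": 0.12,
        }
    )
    background_tag_fraction: float = 0.02
    cleavage_fraction: float = 0.7
    adapter3: str = "TGGAATTCTCGG"
    degradome_adaptor: str = "CAGCAG"
    degradome_tag_len: int = 20
    n_cleavage_sites: int = 10
    qpcr_noise_sd: float = 0.0

    def __post_init__(self):
        if self.library_depth <= 0:
            raise ValueError("depth must be > 0")
        fr = dict(self.contaminant_fractions)
        fr["_background"] = self.background_tag_fraction
        for k, v in fr.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {k}={v} outside [0, 1]")
        if sum(fr.values()) > 1.0:
            raise ValueError("contaminant fractions sum above 1")
        if not 0.0 <= self.tissue_exclusive_fraction <= 1.0:
            raise ValueError("tissue_exclusive_fraction outside [0, 1]")
        if not 0.0 <= self.cleavage_fraction <= 1.0:
            raise ValueError("cleavage_fraction outside [0, 1]")
        if self.n_tissues < 1 or self.n_tissues > len(TISSUES):
            raise ValueError(f"n_tissues must be in [1, {len(TISSUES)}]")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUES[: self.n_tissues]


@dataclass
class GroundTruth:
    """Planted truth plus the reference sets the pipeline consumes."""

    # (name, sequence, per-tissue abundance weights)
    planted_matures: list[tuple[str, str, dict[str, float]]]
    # (locus name, precursor sequence, mature offset, expected per-criterion verdicts)
    planted_precursors: list[tuple[str, str, int, dict[str, bool]]]
    # (miRNA name, transcript id, cleavage position 1-based, expected category)
    planted_cleavages: list[tuple[str, str, int, int]]
    known_matures: dict[str, str] = field(default_factory=dict)
    known_precursors: dict[str, str] = field(default_factory=dict)
    genome: dict[str, str] = field(default_factory=dict)
    contaminants: dict[str, list[str]] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    novel_matures: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# precursor construction


_PAIR_SETS = {
    "mixed": [("G", "C"), ("C", "G"), ("A", "T"), ("T", "A")],
    "gc": [("G", "C"), ("C", "G")],
    "gu": [("G", "T")],  # weak wobble-only stem (DNA alphabet; T reads as U)
}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def make_precursor(
    stem_bp: int,
    loop_len: int,
    mature_len: int,
    bulges: list[tuple[int, int, int]] = (),
    seed: int = 0,
    mature_offset: int = 0,
    mature_seq: str | None = None,
    pair_alphabet: str = "mixed",
    gc_weight: float = 0.6,
    loop_alphabet: str = "AC",
    max_tries: int = 300,
) -> tuple[str, int]:
    """Construct a hairpin precursor with prescribed stem geometry.

    The 5' arm carries ``stem_bp`` paired bases; each bulge spec
    ``(after_pair, n5, n3)`` inserts ``n5`` unpaired nucleotides on the 5'
    arm and ``n3`` on the 3' arm between stem pairs ``after_pair`` and
    ``after_pair + 1`` (pairs counted 1-based from the hairpin base).  The
    mature spans ``mature_len`` nt starting at ``mature_offset`` within the
    precursor (it may run into the terminal loop).  The returned DNA
    sequence is verified to fold into exactly the intended structure under
    :func:`mirforge.fold.fold`; construction is re-sampled (seeded) until it
    does.

    Returns ``(sequence, mature_offset)``.
    """
    if stem_bp < 1:
        raise ValueError("stem_bp must be >= 1")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    arm5_len = stem_bp + sum(b[1] for b in bulges)
    if mature_offset < 0 or mature_offset + mature_len > arm5_len + loop_len:
        raise ValueError(
            f"mature ({mature_offset}+{mature_len}) does not fit the 5' arm "
            f"({arm5_len} nt) plus loop"
        )
    if mature_seq is not None and len(mature_seq) != mature_len:
        raise ValueError("mature_seq length must equal mature_len")
    by_after = {}
    for after, n5, n3 in bulges:
        if not 1 <= after < stem_bp:
            raise ValueError(f"bulge after pair {after} outside stem")
        by_after.setdefault(after, []).append((n5, n3))

    rng = random.Random(seed)
    pairs = _PAIR_SETS[pair_alphabet]
    for _ in range(max_tries):
        arm5, arm3, db5, db3 = [], [], [], []
        for k in range(1, stem_bp + 1):
            pos5 = len(arm5)
            if mature_seq is not None and mature_offset <= pos5 < mature_offset + mature_len:
                x = mature_seq[pos5 - mature_offset]
                y = _COMP[x]
            elif pair_alphabet == "mixed":
                x, y = (
                    rng.choice(_PAIR_SETS["gc"])
                    if rng.random() < gc_weight
                    else rng.choice([("A", "T"), ("T", "A")])
                )
            else:
                x, y = rng.choice(pairs)
            arm5.append(x)
            arm3.append(y)
            db5.append("(")
            db3.append(")")
            for n5, n3 in by_after.get(k, ()):
                arm5 += ["A"] * n5
                db5 += ["."] * n5
                arm3 += ["C"] * n3
                db3 += ["."] * n3
        loop = [rng.choice(loop_alphabet) for _ in range(loop_len)]
        seq = "".join(arm5) + "".join(loop) + "".join(arm3[::-1])
        intended = "".join(db5) + "." * loop_len + "".join(db3[::-1])
        structure, _energy = fold(seq)
        if structure == intended:
            return seq, mature_offset
    raise ValueError(
        "could not realize the requested hairpin spec; it may be infeasible"
    )


#: per-criterion construction recipes: (criterion key or None for the
#: passing archetype, make_precursor keyword arguments)
_SUITE_DESIGNS: list[tuple[str | None, dict]] = [
    (None, dict(stem_bp=24, loop_len=8, mature_len=21)),
    ("stem_bulge", dict(stem_bp=24, loop_len=8, mature_len=21, bulges=[(22, 0, 13)])),
    ("stem_pairs", dict(stem_bp=14, loop_len=24, mature_len=14, pair_alphabet="gc", loop_alphabet="A")),
    ("free_energy", dict(stem_bp=16, loop_len=18, mature_len=16, pair_alphabet="gu", loop_alphabet="A")),
    ("hairpin_length", dict(stem_bp=16, loop_len=8, mature_len=16)),
    ("loop_length", dict(stem_bp=24, loop_len=210, mature_len=21, pair_alphabet="gc", loop_alphabet="A")),
    ("mature_bulge", dict(stem_bp=24, loop_len=8, mature_len=21, bulges=[(10, 5, 0)])),
    (
        "mature_biased_errors",
        dict(stem_bp=24, loop_len=8, mature_len=21, bulges=[(10, 4, 3)]),
    ),
    (
        "mature_biased_bulges",
        dict(
            stem_bp=24,
            loop_len=8,
            mature_len=21,
            bulges=[(5, 1, 0), (10, 1, 0), (15, 1, 0)],
        ),
    ),
    (
        "mature_errors",
        dict(
            stem_bp=24,
            loop_len=8,
            mature_len=21,
            bulges=[(5, 2, 2), (10, 2, 2), (14, 1, 1)],
        ),
    ),
    (
        "mature_pairs",
        dict(stem_bp=24, loop_len=8, mature_len=13, bulges=[(4, 1, 1), (8, 1, 1)]),
    ),
    ("mature_pct_in_stem", dict(stem_bp=24, loop_len=8, mature_len=21, mature_offset=9)),
]


def build_criterion_suite(
    seed: int = 0, thresholds: CriteriaThresholds | None = None
) -> list[dict]:
    """One criteria-passing archetype plus one targeted violator per
    criterion, each verified at construction to fail exactly the intended
    criterion (and nothing else) under the default thresholds.

    Returns dicts with ``label``, ``target`` (criterion key or None),
    ``sequence``, ``mature_span`` and ``expected_verdicts``.
    """
    out = []
    for k, (target, kw) in enumerate(_SUITE_DESIGNS):
        for attempt in range(50):
            seq, moff = make_precursor(seed=seed + 1000 * k + attempt, **kw)
            span = (moff, moff + kw["mature_len"] - 1)
            structure, energy = fold(seq)
            cand = HairpinCandidate(
                "construct", 1, len(seq), "+", seq.replace("T", "U"), structure,
                energy, span,
            )
            m = compute_metrics(cand)
            ok, verdicts = passes_criteria(m, thresholds)
            expected = {key: (key != target) for key in verdicts}
            if verdicts == expected:
                out.append(
                    {
                        "label": target or "pass",
                        "target": target,
                        "sequence": seq,
                        "mature_span": span,
                        "expected_verdicts": expected,
                        "metrics": m,
                    }
                )
                break
        else:
            raise RuntimeError(f"criterion construct {target!r} failed to verify")
    return out


# ---------------------------------------------------------------------------
# ground truth and sRNA libraries


def _rand_seq(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


def _matches_contaminant(seq: str, contaminants: dict[str, list[str]]) -> bool:
    rc = revcomp(seq)
    return any(
        seq in ref or rc in ref for refs in contaminants.values() for ref in refs
    )


def _draw_mature(
    rng: random.Random,
    adapter3: str,
    contaminants: dict[str, list[str]],
    existing: dict[str, str],
) -> str:
    """A clean, unambiguous mature sequence: passes the junk screen, carries
    no adapter seed, matches no contaminant, and is not confusable with any
    already-drawn mature under the end-shift/1-mismatch mapping rule."""
    while True:
        n = rng.choice((20, 21, 21, 21, 22))
        seq = _rand_seq(rng, n)
        if is_junk(seq)[0]:
            continue
        if adapter3[:6] in seq:
            continue
        if _matches_contaminant(seq, contaminants):
            continue
        if map_to_matures(seq, existing):
            continue
        return seq


def build_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw reference sets and planted miRNAs/loci for a configuration."""
    rng = random.Random(config.seed)
    contaminants = {
        cls: [_rand_seq(rng, 400) for _ in range(2)]
        for cls in ("rRNA", "tRNA", "snoRNA", "snRNA", "other_Rfam", "repeat")
    }

    known_matures: dict[str, str] = {}
    known_precursors: dict[str, str] = {}
    planted: list[tuple[str, str, dict[str, float]]] = []
    tissues = config.tissues
    for i in range(config.n_known_mirnas):
        name = f"smi-miR{1000 + i}"
        seq = _draw_mature(rng, config.adapter3, contaminants, known_matures)
        known_matures[name] = seq
        known_precursors[name] = _rand_seq(rng, 10) + seq + _rand_seq(rng, 10)
        # the first miRNA is forced broadly expressed so every tissue has
        # at least one expressed planted mature
        exclusive = i > 0 and rng.random() < config.tissue_exclusive_fraction
        if exclusive:
            t = tissues[i % len(tissues)]
            ab = {x: (rng.lognormvariate(3.0, 0.8) if x == t else 0.0) for x in tissues}
        else:
            ab = {x: rng.lognormvariate(3.0, 0.8) for x in tissues}
        planted.append((name, seq, ab))

    # novel loci: mature on the 5' arm of a verified criteria-passing
    # hairpin embedded in a contig; flanks use a non-pairing two-letter
    # alphabet so the planted hairpin is the window's unique stable fold
    genome: dict[str, str] = {}
    novel_matures: dict[str, str] = {}
    planted_precursors: list[tuple[str, str, int, dict[str, bool]]] = []
    all_matures = dict(known_matures)
    for i in range(config.n_novel_loci):
        name = f"smi-novel-{i + 1}"
        for attempt in range(50):
            seq = _draw_mature(rng, config.adapter3, contaminants, all_matures)
            try:
                prec, moff = make_precursor(
                    stem_bp=24,
                    loop_len=8,
                    mature_len=len(seq),
                    seed=config.seed * 1009 % (2**31 - 1) + 67 * i + attempt,
                    mature_seq=seq,
                )
            except ValueError:
                continue
            structure, energy = fold(prec)
            cand = HairpinCandidate(
                name, 1, len(prec), "+", prec.replace("T", "U"), structure,
                energy, (moff, moff + len(seq) - 1),
            )
            ok, verdicts = passes_criteria(compute_metrics(cand))
            if not ok:
                continue
            # the pipeline folds the whole tag+flank window, not the bare
            # precursor: verify the planted locus is recovered through the
            # exact discovery path before accepting it
            contig = _rand_seq(rng, 60, "AC") + prec + _rand_seq(rng, 140, "AC")
            from .identify import evaluate_window, extract_flanks

            recovered = any(
                evaluate_window(w)[2]
                for w in extract_flanks({"novel": contig}, seq)
            )
            if recovered:
                break
        else:
            raise RuntimeError("could not construct a passing novel locus")
        all_matures[name] = seq
        novel_matures[name] = seq
        genome[f"novel_contig_{i + 1}"] = contig
        planted_precursors.append((f"novel_contig_{i + 1}", prec, 60 + moff, verdicts))
        exclusive = rng.random() < config.tissue_exclusive_fraction
        if exclusive:
            t = tissues[(i + 1) % len(tissues)]
            ab = {x: (rng.lognormvariate(2.0, 0.6) if x == t else 0.0) for x in tissues}
        else:
            ab = {x: rng.lognormvariate(2.0, 0.6) for x in tissues}
        planted.append((name, seq, ab))

    for i in range(config.n_background_loci):
        genome[f"background_contig_{i + 1}"] = _rand_seq(rng, 300)

    return GroundTruth(
        planted_matures=planted,
        planted_precursors=planted_precursors,
        planted_cleavages=[],
        known_matures=known_matures,
        known_precursors=known_precursors,
        genome=genome,
        contaminants=contaminants,
        novel_matures=novel_matures,
    )


_JUNK_RULE_NAMES = ("2N", "7A", "8C", "6G", "7T", "dimer", "trimer", "tetramer")


def _make_junk_insert(rng: random.Random, rule: str) -> str:
    n = rng.randint(18, 25)
    if rule == "2N":
        s = list(_rand_seq(rng, n))
        i, j = rng.sample(range(n), 2)
        s[i] = s[j] = "N"
        return "".join(s)
    if rule in ("7A", "8C", "6G", "7T"):
        base, thr = rule[-1], int(rule[:-1])
        rest = _rand_seq(rng, n - thr, "ACGT".replace(base, ""))
        cut = rng.randint(0, len(rest))
        return rest[:cut] + base * thr + rest[cut:]
    unit_len, units = {"dimer": (2, 10), "trimer": (3, 6), "tetramer": (4, 5)}[rule]
    while True:
        unit = _rand_seq(rng, unit_len)
        if len(set(unit)) > 1:  # avoid collapsing into a homopolymer rule
            break
    return (unit * units)[: max(n, unit_len * units)]


def _make_no_adapter_read(rng: random.Random, adapter3: str) -> str:
    while True:
        seq = _rand_seq(rng, READ_LEN)
        if trim_adapter(seq, adapter3) is None:
            return seq


def _contaminant_read(
    rng: random.Random, refs: list[str], adapter3: str
) -> str:
    while True:
        ref = rng.choice(refs)
        n = rng.randint(18, 25)
        start = rng.randint(0, len(ref) - n)
        frag = ref[start : start + n]
        if rng.random() < 0.5:
            frag = revcomp(frag)
            if frag not in ref and revcomp(frag) not in ref:
                continue
        if is_junk(frag)[0] or adapter3[:6] in frag:
            continue
        return _finish_read(frag, adapter3)


def _finish_read(insert: str, adapter3: str) -> str:
    return (insert + adapter3 + ADAPTER_FILLER)[:READ_LEN]


def simulate_srna_libraries(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per-tissue raw reads (36 nt) and a per-read provenance table.

    Each library holds exactly ``library_depth`` reads: planted miRNA reads
    (insert + 3' adapter + filler) at multinomial abundance, contaminant
    substrings, junk reads covering all eight low-complexity rules,
    adapter-less reads, and background genomic tags.
    """
    rng = random.Random(config.seed + 1)
    nprng = np.random.default_rng((config.seed * 7919 + 11) % (2**31 - 1))
    depth = config.library_depth
    libraries: dict[str, list[str]] = {}
    prov_rows = []

    bg_contigs = [s for n, s in truth.genome.items() if n.startswith("background_")]
    bg_tags: list[str] = []
    n_bg_tags = max(1, config.n_background_loci)
    while bg_contigs and len(bg_tags) < n_bg_tags:
        contig = rng.choice(bg_contigs)
        start = rng.randint(0, len(contig) - 21)
        tag = contig[start : start + 21]
        if is_junk(tag)[0] or config.adapter3[:6] in tag:
            continue
        if map_to_matures(tag, truth.known_matures):
            continue
        bg_tags.append(tag)

    class_counts = {
        cls: int(frac * depth) for cls, frac in config.contaminant_fractions.items()
    }
    n_bg = int(config.background_tag_fraction * depth) if bg_tags else 0
    n_mirna = depth - sum(class_counts.values()) - n_bg

    names = [m[0] for m in truth.planted_matures]
    seqs = {m[0]: m[1] for m in truth.planted_matures}
    for tissue in config.tissues:
        reads: list[tuple[str, str, str]] = []  # (read, class, detail)
        weights = np.array(
            [m[2][tissue] for m in truth.planted_matures], dtype=float
        )
        if weights.sum() == 0:
            raise RuntimeError(f"no planted mature expressed in {tissue}")
        counts = nprng.multinomial(n_mirna, weights / weights.sum())
        for name, c in zip(names, counts):
            read = _finish_read(seqs[name], config.adapter3)
            reads += [(read, "mirna", name)] * int(c)
        for cls, n in class_counts.items():
            if cls == "junk":
                for k in range(n):
                    rule = _JUNK_RULE_NAMES[k % len(_JUNK_RULE_NAMES)]
                    reads.append(
                        (
                            _finish_read(_make_junk_insert(rng, rule), config.adapter3),
                            "junk",
                            rule,
                        )
                    )
            elif cls == "no_adapter":
                reads += [
                    (_make_no_adapter_read(rng, config.adapter3), "no_adapter", "")
                    for _ in range(n)
                ]
            else:
                reads += [
                    (
                        _contaminant_read(rng, truth.contaminants[cls], config.adapter3),
                        cls,
                        "",
                    )
                    for _ in range(n)
                ]
        for k in range(n_bg):
            tag = bg_tags[k % len(bg_tags)]
            reads.append((_finish_read(tag, config.adapter3), "background", tag))
        rng.shuffle(reads)
        libraries[tissue] = [r[0] for r in reads]
        prov_rows += [
            {"library": tissue, "read_index": i, "classe": r[1], "detail": r[2]}
            for i, r in enumerate(reads)
        ]
    prov = pd.DataFrame(prov_rows).rename(columns={"classe": "class"})
    return libraries, prov


# ---------------------------------------------------------------------------
# degradome simulation

# per-category transcript plans: number of co-planted sites, the count each
# site receives, decoy peaks elsewhere, and 1-count background positions.
# Multi-site plans only exist where the rule admits several equal peaks
# (shared maxima for 1; sub-maximal for 2/3; singletons for 4).
_CATEGORY_PLANS = {
    0: dict(n_sites=1, site=6, decoys=(2,), background=3),
    1: dict(n_sites=2, site=5, decoys=(), background=3),
    2: dict(n_sites=3, site=3, decoys=(8,), background=4),
    3: dict(n_sites=3, site=2, decoys=(3, 3, 3), background=0),
    4: dict(n_sites=3, site=1, decoys=(3, 2), background=0),
}


def simulate_degradome(
    config: SimulationConfig,
    truth: GroundTruth,
    transcripts: dict[str, str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Degradome raw reads (5' adaptor + 36-nt 5'-end tags) with planted
    cleavage sites realizing each requested category against background.

    Builds transcripts (embedding the antisense of a planted miRNA at each
    site) unless given; category plans cycle 0-4 across transcripts until
    ``config.n_cleavage_sites`` sites are planted.  ``cleavage_fraction``
    controls the uniform background: at 1.0 every on-transcript tag sits at
    a planted position (decoys and background are dropped, so realized
    categories are recomputed); below 1.0 the planned profiles are kept and
    extra 1-count background positions are added.  Fills
    ``truth.planted_cleavages`` and ``truth.transcripts``; returns the raw
    reads and the transcript set.
    """
    rng = random.Random(config.seed + 2)
    matures = truth.planted_matures
    if not matures:
        raise ValueError("ground truth has no planted matures")
    if transcripts is None:
        transcripts = {}
    reads: list[str] = []
    truth.planted_cleavages = []
    pure = config.cleavage_fraction >= 1.0

    n_planted = 0
    t_index = 0
    mat_index = 0
    while n_planted < config.n_cleavage_sites:
        cat = t_index % 5
        plan = _CATEGORY_PLANS[cat]
        n_sites = min(plan["n_sites"], config.n_cleavage_sites - n_planted)
        if pure:
            n_sites = min(n_sites, 1)
        t_index += 1
        tid = f"transcript_{t_index}"
        tlen = 300
        body = list(_rand_seq(rng, tlen))
        occupied: list[tuple[int, int]] = []  # (0-based embed start, length)
        site_info = []
        for _ in range(n_sites):
            name, mseq, _ab = matures[mat_index % len(matures)]
            mat_index += 1
            L = len(mseq)
            while True:
                s = rng.randint(10, tlen - L - 60)
                if all(s + L + 2 <= o or o + ol + 2 <= s for o, ol in occupied):
                    break
            occupied.append((s, L))
            body[s : s + L] = revcomp(mseq)
            cleavage = s + L - 9  # 1-based base paired to miRNA position 10
            site_info.append((name, cleavage))
        tseq = "".join(body)
        profile: dict[int, int] = {c: plan["site"] for _, c in site_info}
        used = set(profile)

        def free_pos():
            while True:
                p = rng.randint(10, tlen - READ_LEN)
                if p not in used:
                    used.add(p)
                    return p

        if not pure:
            for dc in plan["decoys"]:
                profile[free_pos()] = dc
            n_bg = plan["background"] + int(
                round(4 * (1.0 - config.cleavage_fraction))
            )
            for _ in range(n_bg):
                profile[free_pos()] = 1
        tplot = TPlot(tid, tlen, profile)
        transcripts[tid] = tseq
        for name, cleavage in site_info:
            realized = categorize(cleavage, tplot)
            # a clamped plan (fewer co-planted sites than designed) can
            # legitimately realize a different category; the stored truth is
            # always the realized one
            if not pure and n_sites == plan["n_sites"] and realized != cat:
                raise RuntimeError(f"category plan {cat} realized {realized}")
            truth.planted_cleavages.append((name, tid, cleavage, realized))
            n_planted += 1
        for pos, c in profile.items():
            frag = tseq[pos - 1 : pos - 1 + READ_LEN]
            reads += [config.degradome_adaptor + frag] * c

    # background-only transcripts with uniform tags (no cleavage site)
    n_background_tx = 0 if pure else 3
    for b in range(n_background_tx):
        tid = f"background_tx_{b + 1}"
        tseq = _rand_seq(rng, 300)
        transcripts[tid] = tseq
        for _ in range(4):
            p = rng.randint(1, 300 - READ_LEN)
            reads.append(config.degradome_adaptor + tseq[p - 1 : p - 1 + READ_LEN])

    # reads failing the adaptor gate
    n_no_adaptor = int(len(reads) * 0.15)
    for _ in range(n_no_adaptor):
        r = _rand_seq(rng, READ_LEN + len(config.degradome_adaptor))
        if r.startswith(config.degradome_adaptor):
            continue
        reads.append(r)
    rng.shuffle(reads)
    truth.transcripts = dict(transcripts)
    return reads, transcripts


# ---------------------------------------------------------------------------
# qPCR simulation


def simulate_qpcr(
    true_fold_changes: dict[str, dict[str, float]],
    ct_ref: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    reference_gene: str = "actin7",
    gene_offset: float = 3.0,
) -> pd.DataFrame:
    """Ct table realizing known fold changes under the comparative-Ct model.

    ``true_fold_changes[gene][sample]`` is the relative quantity of the gene
    in that sample (the calibrator sample should carry 1.0).  Target Ct is
    ``ct_ref - log2(fold) + gene_offset + noise``; reference-gene Ct is
    ``ct_ref + noise``.  With ``noise_sd=0`` the 2^-ddCt method recovers the
    fold changes exactly.
    """
    rng = random.Random(seed)
    rows = []
    samples = sorted({s for g in true_fold_changes.values() for s in g})
    for sample in samples:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample": sample,
                    "gene": reference_gene,
                    "replicate": rep,
                    "ct": ct_ref + rng.gauss(0.0, noise_sd),
                }
            )
    for gene, per_sample in true_fold_changes.items():
        for sample, fold in per_sample.items():
            if fold <= 0:
                raise ValueError(f"fold change must be > 0 ({gene}/{sample})")
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "replicate": rep,
                        "ct": ct_ref
                        - np.log2(fold)
                        + gene_offset
                        + rng.gauss(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file output


def simulate_all(config: SimulationConfig, outdir) -> GroundTruth:
    """Generate and write every input the pipeline consumes.

    Layout under ``outdir``: per-tissue ``srna_<tissue>.fastq``,
    ``degradome.fastq``, reference FASTAs (``mature.fa``, ``hairpin.fa``,
    ``genome.fa``, ``transcripts.fa``, one FASTA per contaminant class under
    ``contaminants/``), ``qpcr_ct.tsv`` and ground-truth TSVs under
    ``truth/``.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth = build_ground_truth(config)
    libraries, prov = simulate_srna_libraries(config, truth)
    for tissue, reads in libraries.items():
        _write_fastq(out / f"srna_{tissue}.fastq", reads, f"{tissue}")
    deg_reads, transcripts = simulate_degradome(config, truth)
    _write_fastq(out / "degradome.fastq", deg_reads, "deg")

    _write_fasta(out / "mature.fa", truth.known_matures)
    _write_fasta(out / "hairpin.fa", truth.known_precursors)
    _write_fasta(out / "genome.fa", truth.genome)
    _write_fasta(out / "transcripts.fa", transcripts)
    cont_dir = out / "contaminants"
    cont_dir.mkdir(exist_ok=True)
    for cls, refs in truth.contaminants.items():
        _write_fasta(
            cont_dir / f"{cls}.fa", {f"{cls}_{i + 1}": s for i, s in enumerate(refs)}
        )

    folds = {
        name: {t: (ab[t] / ab[config.tissues[0]] if ab[config.tissues[0]] else 1.0)
               for t in config.tissues}
        for name, _seq, ab in truth.planted_matures[:4]
        if all(ab[t] > 0 for t in config.tissues)
    }
    if folds:
        ct = simulate_qpcr(
            folds, noise_sd=config.qpcr_noise_sd, seed=config.seed + 3
        )
        ct.to_csv(out / "qpcr_ct.tsv", sep="\t", index=False)

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {"name": n, "sequence": s, **{f"ab_{t}": ab[t] for t in config.tissues}}
            for n, s, ab in truth.planted_matures
        ]
    ).to_csv(tdir / "matures.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"locus": l, "sequence": s, "mature_offset": o,
             "passes_all": all(v.values())}
            for l, s, o, v in truth.planted_precursors
        ]
    ).to_csv(tdir / "precursors.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.planted_cleavages,
        columns=["mirna", "transcript", "position", "category"],
    ).to_csv(tdir / "cleavages.tsv", sep="\t", index=False)
    prov.to_csv(tdir / "read_provenance.tsv", sep="\t", index=False)
    return truth


def _write_fastq(path, reads: list[str], prefix: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, r in enumerate(reads):
        rec = SeqRecord(Seq(r), id=f"{prefix}_{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def _write_fasta(path, seqs: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
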