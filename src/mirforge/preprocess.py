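"""Raw small-RNA read cleaning: adapter trimming, junk and length filters,
tag collapsing, and contaminant triage.

The cascade is fixed: 3' adapter removal, junk screen, length filter
(18-25 nt inserts), collapse to unique tags with per-library counts, then
annotation against non-miRNA reference sets (rRNA, tRNA, snoRNA, snRNA,
other RNA families, repeats).  The filter report mirrors the layout of a
library-distribution summary table: one row per removal class, total and
unique counts per library, with the family row ("Rfam") being the sum of the
individually triaged family classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .identify import revcomp

__all__ = [
    "JunkRules",
    "UniqueTag",
    "trim_adapter",
    "is_junk",
    "length_filter",
    "collapse",
    "triage",
    "run_preprocess",
    "FAMILY_CLASSES",
    "DEFAULT_PRIORITY",
]

#: contaminant classes grouped under the "Rfam" summary row
FAMILY_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA", "other_Rfam")
#: default primary-annotation priority (summary-table row order)
DEFAULT_PRIORITY = ("rRNA", "tRNA", "snoRNA", "snRNA", "other_Rfam", "repeat")


@dataclass(frozen=True)
class JunkRules:
    """Low-complexity ("junk") screen thresholds.

    Homopolymer thresholds count the longest *consecutive* run of each base
    (total-occurrence counting is a documented alternative reading; set
    ``consecutive=False`` for it).  k-mer thresholds count tandem repeats of
    a fixed 2-/3-/4-mer unit.
    """

    max_n: int = 2  # >= max_n ambiguous bases anywhere
    run_a: int = 7
    run_c: int = 8
    run_g: int = 6
    run_t: int = 7
    dimer_units: int = 10
    trimer_units: int = 6
    tetramer_units: int = 5
    consecutive: bool = True


def trim_adapter(
    read: str, adapter3: str, min_overlap: int = 6
) -> str | None:
    """Insert upstream of the leftmost 3' adapter occurrence.

    Falls back to the longest suffix-prefix overlap (read 3' end vs adapter
    5' end) of at least ``min_overlap`` exact bases.  Returns ``None`` when
    no adapter is found (read removed as "3ADT not found").
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    read = read.upper()
    adapter3 = adapter3.upper()
    k = read.find(adapter3)
    if k >= 0:
        return read[:k]
    top = min(len(adapter3) - 1, len(read))
    for n in range(top, min_overlap - 1, -1):
        if read.endswith(adapter3[:n]):
            return read[: len(read) - n]
    return None


def _max_run(seq: str, base: str) -> int:
    best = cur = 0
    for c in seq:
        cur = cur + 1 if c == base else 0
        best = max(best, cur)
    return best


def _max_tandem(seq: str, k: int) -> int:
    """Largest number of consecutive repeats of any k-mer unit in seq."""
    n = len(seq)
    best = 0
    for s in range(n - k + 1):
        unit = seq[s : s + k]
        reps = 1
        p = s + k
        while p + k <= n and seq[p : p + k] == unit:
            reps += 1
            p += k
        best = max(best, reps)
    return best


def is_junk(seq: str, rules: JunkRules | None = None) -> tuple[bool, str | None]:
    """Screen a sequence against the low-complexity rules.

    Returns ``(True, rule)`` naming the first triggered rule, or
    ``(False, None)``.
    """
    if not seq:
        raise ValueError("empty sequence")
    r = rules or JunkRules()
    s = seq.upper()
    if s.count("N") >= r.max_n:
        return True, f">={r.max_n}N"
    homo = [("A", r.run_a), ("C", r.run_c), ("G", r.run_g), ("T", r.run_t)]
    for base, thr in homo:
        count = _max_run(s, base) if r.consecutive else s.count(base)
        if count >= thr:
            return True, f">={thr}{base}"
    for k, thr, label in (
        (2, r.dimer_units, "Dimer"),
        (3, r.trimer_units, "Trimer"),
        (4, r.tetramer_units, "Tetramer"),
    ):
        if _max_tandem(s, k) >= thr:
            return True, f">={thr} {label}"
    return False, None


def length_filter(seq: str, min_len: int = 18, max_len: int = 25) -> bool:
    """Keep iff min_len <= len(seq) <= max_len (both inclusive)."""
    return min_len <= len(seq) <= max_len


@dataclass
class UniqueTag:
    """A distinct clean sequence with per-library counts."""

    sequence: str
    counts: dict[str, int]
    annotation: str = "clean"
    matched_classes: tuple[str, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def collapse(reads: list[tuple[str, str]]) -> list[UniqueTag]:
    """Collapse ``(sequence, library)`` records into unique tags.

    Output is sorted by descending total count then sequence, so repeated
    runs produce identical files.
    """
    per_seq: dict[str, Counter] = {}
    for seq, lib in reads:
        per_seq.setdefault(seq, Counter())[lib] += 1
    tags = [UniqueTag(s, dict(c)) for s, c in per_seq.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def triage(
    tag: str,
    references: dict[str, list[str]],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> tuple[str, tuple[str, ...]]:
    """Annotate a tag against contaminant reference sets.

    A tag matches a class when it is an exact substring of any reference
    sequence of that class, on either strand.  Returns the highest-priority
    matching class (or ``"clean"``) plus the full tuple of matching classes
    for overlap bookkeeping.
    """
    tag = tag.upper()
    rc = revcomp(tag)
    matched = []
    for cls in priority:
        refs = references.get(cls, [])
        if any(tag in ref.upper() or rc in ref.upper() for ref in refs):
            matched.append(cls)
    if matched:
        return matched[0], tuple(matched)
    return "clean", ()


def run_preprocess(
    libraries: dict[str, list[str]],
    references: dict[str, list[str]] | None = None,
    adapter3: str = "TGGAATTCTCGG",
    min_overlap: int = 6,
    junk_rules: JunkRules | None = None,
    min_len: int = 18,
    max_len: int = 25,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> tuple[list[UniqueTag], pd.DataFrame]:
    """Run the full cascade over raw reads grouped by library.

    Returns the clean unique tags (annotation ``clean``) together with all
    annotated contaminant tags, and the filter report.  The report counts
    reads once per primary class; family classes are additionally summed
    into the ``Rfam`` row, and the overlap of each tag is retained on the
    tag itself (``matched_classes``).
    """
    references = references or {}
    libs = list(libraries)
    rows = [
        "Raw reads",
        "3ADT & length filter",
        "Junk reads",
        "Rfam",
        "Repeats",
        "rRNA",
        "tRNA",
        "snoRNA",
        "snRNA",
        "other Rfam RNA",
        "Clean reads",
    ]
    total = {r: Counter() for r in rows}
    uniq = {r: Counter() for r in rows}

    kept: list[tuple[str, str]] = []
    removed_adapter_or_len: dict[str, Counter] = {lib: Counter() for lib in libs}
    junk_seqs: dict[str, Counter] = {lib: Counter() for lib in libs}
    for lib, reads in libraries.items():
        total["Raw reads"][lib] = len(reads)
        uniq["Raw reads"][lib] = len(set(reads))
        for read in reads:
            insert = trim_adapter(read, adapter3, min_overlap)
            if insert is None:
                removed_adapter_or_len[lib][read] += 1
                continue
            junk, _rule = is_junk(insert, junk_rules) if insert else (False, None)
            if junk:
                junk_seqs[lib][insert] += 1
                continue
            if not length_filter(insert, min_len, max_len):
                removed_adapter_or_len[lib][insert] += 1
                continue
            kept.append((insert, lib))
    for lib in libs:
        total["3ADT & length filter"][lib] = sum(removed_adapter_or_len[lib].values())
        uniq["3ADT & length filter"][lib] = len(removed_adapter_or_len[lib])
        total["Junk reads"][lib] = sum(junk_seqs[lib].values())
        uniq["Junk reads"][lib] = len(junk_seqs[lib])

    tags = collapse(kept)
    class_row = {
        "rRNA": "rRNA",
        "tRNA": "tRNA",
        "snoRNA": "snoRNA",
        "snRNA": "snRNA",
        "other_Rfam": "other Rfam RNA",
        "repeat": "Repeats",
    }
    for tag in tags:
        primary, matched = triage(tag.sequence, references, priority)
        tag.annotation = primary
        tag.matched_classes = matched
        row = class_row.get(primary, "Clean reads")
        for lib, c in tag.counts.items():
            total[row][lib] += c
            uniq[row][lib] += 1
            if primary in FAMILY_CLASSES:
                total["Rfam"][lib] += c
                uniq["Rfam"][lib] += 1

    data = {}
    for lib in libs:
        data[(lib, "total")] = [total[r].get(lib, 0) for r in rows]
        data[(lib, "unique")] = [uniq[r].get(lib, 0) for r in rows]
    report = pd.DataFrame(data, index=rows)
    report.columns = pd.MultiIndex.from_tuples(report.columns)
    return tags, report
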