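"""IsomiR cataloguing: align small-RNA reads to mature/hairpin references,
classify 5'/3' end variation and templating, extract seeds, call 5' isomiRs,
and summarise seed groups and nontemplated tail composition.

Conventions
-----------
* Offsets are in hairpin coordinates.  ``five_prime_offset`` is
  (mature 5' start − read 5' start), so a read whose 5' end lies one
  nucleotide downstream of the annotated start (a shorter read, shifted in
  the 3' direction) has offset −1.  ``three_prime_offset`` is
  (templated read 3' end − mature 3' end).
* A read's 3' extension is explained as *templated* genomic continuation
  greedily, longest match first; only the unexplainable suffix is called a
  nontemplated tail.  This is the conservative choice — it minimises
  nontemplated calls.
* Matching is exact (no mismatches) against hairpin plus genomic flanks.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._seq import normalize_rna

CATEGORIES = ("canonical", "5prime_only", "3prime_only", "mixed")

#: Default minimum exactly-matching read core, in nt.
MIN_CORE = 16
#: Default largest |5' offset| considered when anchoring a read.
MAX_SHIFT = 6


@dataclass(frozen=True)
class MatureRef:
    """A mature miRNA annotation within its hairpin.

    ``start`` is the 0-based offset of the mature 5' end within the hairpin
    sequence (not including flanks).
    """

    name: str
    sequence: str
    hairpin_name: str
    start: int
    arm: str = "3p"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if self.start < 0:
            raise ValueError("mature start must be non-negative")


@dataclass(frozen=True)
class Alignment:
    """End-variation of one read relative to one mature reference."""

    five_prime_offset: int
    three_prime_offset: int
    nontemplated_tail: str


@dataclass
class IsomiRRecord:
    """One distinct read sequence assigned to a mature reference."""

    sequence: str
    count: int
    ref: str
    five_prime_offset: int
    three_prime_offset: int
    nontemplated_tail: str
    templated: bool
    seed: str
    category: str
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("read count must be >= 1")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class SeedGroup:
    """All isomiR records of one miRNA sharing a seed heptamer."""

    seed: str
    members: list[IsomiRRecord]
    total_count: int
    fraction_of_mirna: float
    representative: str
    suffix_name: str


@dataclass
class FivePrimeIsomiRCall:
    """One candidate 5' isomiR with its pass/fail flag.

    ``passes`` is True iff |offset| >= 1, count > min_reads and
    fraction > min_fraction (both thresholds strict).
    """

    mirna: str
    sequence: str
    count: int
    fraction: float
    offset: int
    passes: bool


def extract_seed(sequence: str) -> str:
    """Seed heptamer: miRNA positions 2-8 (1-based, inclusive).

    >>> extract_seed("ACCACAGGGUAGAACCACGGAC")
    'CCACAGG'
    """
    s = normalize_rna(sequence)
    if len(s) < 8:
        raise ValueError(f"sequence too short for seed extraction ({len(s)} nt < 8)")
    return s[1:8]


def align_read(
    read: str,
    ref: MatureRef,
    hairpin_context: str,
    mature_start_in_context: int | None = None,
    *,
    min_core: int = MIN_CORE,
    max_shift: int = MAX_SHIFT,
) -> Alignment | None:
    """Anchor a read near a mature reference within its templated context.

    ``hairpin_context`` is the hairpin sequence with genomic flanks attached;
    ``mature_start_in_context`` locates the mature 5' end within it (defaults
    to ``ref.start``, i.e. a context without a 5' flank).

    Returns ``None`` when no exact core match of at least ``min_core`` nt
    anchors within ``max_shift`` nt of the mature 5' end — such reads are
    routed to a reject file by the caller, never raised.
    """
    read = normalize_rna(read)
    ctx = normalize_rna(hairpin_context)
    ms = ref.start if mature_start_in_context is None else mature_start_in_context
    if ctx[ms : ms + len(ref.sequence)] != ref.sequence:
        raise ValueError(
            f"context does not contain mature {ref.name} at position {ms}"
        )

    best: tuple[int, int, int] | None = None  # (core_len, -|offset|, -p)
    best_p = None
    for p in range(max(0, ms - max_shift), min(len(ctx), ms + max_shift + 1)):
        core = _longest_prefix_match(read, ctx, p)
        if core < min_core:
            continue
        key = (core, -abs(ms - p), -p)
        if best is None or key > best:
            best = key
            best_p = p
    if best is None or best_p is None:
        return None

    core_len = best[0]
    five = ms - best_p
    three = (best_p + core_len) - (ms + len(ref.sequence))
    tail = read[core_len:]
    return Alignment(five, three, tail)


def _longest_prefix_match(read: str, ctx: str, p: int) -> int:
    limit = min(len(read), len(ctx) - p)
    i = 0
    while i < limit and read[i] == ctx[p + i]:
        i += 1
    return i


def classify_isomir(alignment: Alignment) -> tuple[str, bool]:
    """Map an alignment to its isomiR category and templated flag.

    canonical <=> offsets (0, 0) and empty tail; the templated flag is True
    iff the nontemplated tail is empty (all extension genome-matched).
    """
    five_var = alignment.five_prime_offset != 0
    three_var = alignment.three_prime_offset != 0 or bool(alignment.nontemplated_tail)
    if not five_var and not three_var:
        category = "canonical"
    elif five_var and not three_var:
        category = "5prime_only"
    elif three_var and not five_var:
        category = "3prime_only"
    else:
        category = "mixed"
    return category, not alignment.nontemplated_tail


@dataclass
class HairpinContext:
    """A hairpin with its genomic flanks, for templated-extension calls."""

    name: str
    hairpin_seq: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        self.hairpin_seq = normalize_rna(self.hairpin_seq)
        self.flank5 = normalize_rna(self.flank5) if self.flank5 else ""
        self.flank3 = normalize_rna(self.flank3) if self.flank3 else ""

    @property
    def context(self) -> str:
        return self.flank5 + self.hairpin_seq + self.flank3

    def mature_start_in_context(self, ref: MatureRef) -> int:
        return len(self.flank5) + ref.start


def build_catalog(
    seq_counts: Iterable[tuple[str, int]],
    refs: Sequence[MatureRef],
    hairpins: Mapping[str, HairpinContext],
    *,
    min_core: int = MIN_CORE,
    max_shift: int = MAX_SHIFT,
) -> tuple[list[IsomiRRecord], list[tuple[str, int]]]:
    """Assign each distinct read sequence to a mature reference.

    A read matching multiple matures is assigned to the reference with the
    smallest |5' offset| (ties broken lexicographically by reference name)
    and flagged ``ambiguous``.  Unassignable reads are returned as rejects.
    """
    records: list[IsomiRRecord] = []
    rejects: list[tuple[str, int]] = []
    for raw_seq, count in seq_counts:
        seq = normalize_rna(raw_seq)
        hits: list[tuple[int, str, Alignment]] = []
        for ref in refs:
            hp = hairpins[ref.hairpin_name]
            aln = align_read(
                seq,
                ref,
                hp.context,
                hp.mature_start_in_context(ref),
                min_core=min_core,
                max_shift=max_shift,
            )
            if aln is not None:
                hits.append((abs(aln.five_prime_offset), ref.name, aln))
        if not hits:
            rejects.append((seq, count))
            continue
        hits.sort(key=lambda h: (h[0], h[1]))
        _, ref_name, aln = hits[0]
        category, templated = classify_isomir(aln)
        records.append(
            IsomiRRecord(
                sequence=seq,
                count=count,
                ref=ref_name,
                five_prime_offset=aln.five_prime_offset,
                three_prime_offset=aln.three_prime_offset,
                nontemplated_tail=aln.nontemplated_tail,
                templated=templated,
                seed=extract_seed(seq),
                category=category,
                ambiguous=len(hits) > 1,
            )
        )
    return records, rejects


def call_5p_isomirs(
    records: Iterable[IsomiRRecord],
    *,
    min_reads: int = 100,
    min_fraction: float = 0.05,
    fraction_denominator: str = "arm_total",
) -> list[FivePrimeIsomiRCall]:
    """Flag 5'-shifted isomiRs passing the strict read-support criteria.

    A call passes iff |5' offset| >= 1, count > ``min_reads`` and
    fraction > ``min_fraction``; records at exactly the thresholds fail.
    ``fraction_denominator`` selects the fraction's denominator: all reads
    of the mature arm (``arm_total``, default) or reads of the canonical
    sequence only (``canonical_only``).
    """
    if fraction_denominator not in ("arm_total", "canonical_only"):
        raise ValueError(f"unknown denominator {fraction_denominator!r}")
    by_mirna: dict[str, list[IsomiRRecord]] = defaultdict(list)
    for rec in records:
        by_mirna[rec.ref].append(rec)

    calls: list[FivePrimeIsomiRCall] = []
    for mirna in sorted(by_mirna):
        recs = by_mirna[mirna]
        if fraction_denominator == "arm_total":
            denom = sum(r.count for r in recs)
        else:
            denom = sum(r.count for r in recs if r.category == "canonical")
        for rec in sorted(recs, key=lambda r: (-r.count, r.sequence)):
            fraction = rec.count / denom if denom else float("nan")
            passes = (
                abs(rec.five_prime_offset) >= 1
                and rec.count > min_reads
                and fraction > min_fraction
            )
            calls.append(
                FivePrimeIsomiRCall(
                    mirna=mirna,
                    sequence=rec.sequence,
                    count=rec.count,
                    fraction=fraction,
                    offset=rec.five_prime_offset,
                    passes=passes,
                )
            )
    return calls


def group_by_seed(
    records: Sequence[IsomiRRecord],
    *,
    name_overrides: Mapping[str, str] | None = None,
) -> list[SeedGroup]:
    """Group one miRNA's records by seed heptamer.

    Groups are sorted by descending total read count (ties by seed string)
    and suffix-named ".1", ".2", ... in that order.  ``name_overrides``
    (seed -> suffix) lets callers reproduce published fixed assignments such
    as TargetScan's, where ".2" is the seed of the original annotation.
    """
    if not records:
        return []
    mirnas = {r.ref for r in records}
    if len(mirnas) > 1:
        raise ValueError(f"records span multiple miRNAs: {sorted(mirnas)}")
    total = sum(r.count for r in records)
    by_seed: dict[str, list[IsomiRRecord]] = defaultdict(list)
    for rec in records:
        by_seed[rec.seed].append(rec)

    groups: list[SeedGroup] = []
    ordered = sorted(
        by_seed.items(), key=lambda kv: (-sum(r.count for r in kv[1]), kv[0])
    )
    for i, (seed, members) in enumerate(ordered, start=1):
        group_total = sum(r.count for r in members)
        rep = max(members, key=lambda r: (r.count, r.sequence)).sequence
        suffix = f".{i}"
        if name_overrides and seed in name_overrides:
            suffix = name_overrides[seed]
        groups.append(
            SeedGroup(
                seed=seed,
                members=sorted(members, key=lambda r: (-r.count, r.sequence)),
                total_count=group_total,
                fraction_of_mirna=group_total / total,
                representative=rep,
                suffix_name=suffix,
            )
        )
    return groups


def tail_composition(records: Iterable[IsomiRRecord]) -> dict[str, int]:
    """Read-weighted counts of A/C/G/U over all nontemplated tail positions."""
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    for rec in records:
        for nt in rec.nontemplated_tail:
            counts[nt] += rec.count
    return counts
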