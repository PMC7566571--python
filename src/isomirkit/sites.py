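"""Canonical seed-match target sites: derive the 6mer/7mer-A1/7mer-m8/8mer
site motifs of a mature miRNA, scan 3'UTRs, and build predicted-target sets.

Site motifs are written 5'->3' in the mRNA sense.  The 6mer is the reverse
complement of miRNA positions 2-7; the 7mer-m8 adds the position-8 match one
base 5' of that core; the "A1" types append a literal adenosine opposite
miRNA position 1 (an identity of the target, not a complement).  At one
anchor position nested types collapse to the strongest:
8mer > 7mer-m8 > 7mer-A1 > 6mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from ._seq import normalize_rna, revcomp_rna

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}


@dataclass(frozen=True)
class SiteMotifSet:
    """The four canonical site strings derived from one mature sequence."""

    isomir: str
    six_mer: str
    seven_a1: str
    seven_m8: str
    eight_mer: str


@dataclass(frozen=True)
class SiteHit:
    """One seed-match occurrence; ``position`` anchors the 6mer core."""

    gene: str
    isomir: str
    position: int
    site_type: str


@dataclass
class TargetSet:
    isomir: str
    genes: set[str]
    min_site_type: str


def site_motifs(mature: str, isomir: str = "") -> SiteMotifSet:
    """Derive the canonical target-site motifs from a mature miRNA sequence.

    >>> site_motifs("ACCACAGGGUAGAACCACGGAC").six_mer
    'CUGUGG'
    """
    seq = normalize_rna(mature)
    if len(seq) < 8:
        raise ValueError(f"mature sequence too short ({len(seq)} nt < 8)")
    six = revcomp_rna(seq[1:7])
    m8 = revcomp_rna(seq[1:8])
    return SiteMotifSet(
        isomir=isomir or seq,
        six_mer=six,
        seven_a1=six + "A",
        seven_m8=m8,
        eight_mer=m8 + "A",
    )


def scan_utr(utr: str, motifs: SiteMotifSet, gene: str = "") -> list[SiteHit]:
    """Find every 6mer-core occurrence in a UTR, promoted to its strongest type.

    Hits are reported in ascending core position; an empty UTR yields an
    empty list.
    """
    seq = normalize_rna(utr) if utr else ""
    core = motifs.six_mer
    m8_base = motifs.seven_m8[0]
    hits: list[SiteHit] = []
    i = seq.find(core)
    while i != -1:
        has_m8 = i >= 1 and seq[i - 1] == m8_base
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        hits.append(SiteHit(gene=gene, isomir=motifs.isomir, position=i, site_type=site_type))
        i = seq.find(core, i + 1)
    return hits


def predict_targets(
    utrome: Mapping[str, str] | Iterable[tuple[str, str]],
    motifs: SiteMotifSet,
    min_site_type: str = "7mer-A1",
) -> TargetSet:
    """Genes whose UTR carries at least one site at or above ``min_site_type``.

    ``utrome`` maps gene identifiers to UTR sequences; duplicate gene
    identifiers are an input error.
    """
    if min_site_type not in SITE_RANK:
        raise ValueError(f"min_site_type must be one of {SITE_TYPES}")
    items = list(utrome.items()) if isinstance(utrome, Mapping) else list(utrome)
    seen: set[str] = set()
    for gene, _ in items:
        if gene in seen:
            raise ValueError(f"duplicate gene identifier in utrome: {gene!r}")
        seen.add(gene)
    min_rank = SITE_RANK[min_site_type]
    genes = {
        gene
        for gene, utr in items
        if any(SITE_RANK[h.site_type] >= min_rank for h in scan_utr(utr, motifs, gene))
    }
    return TargetSet(isomir=motifs.isomir, genes=genes, min_site_type=min_site_type)


def unique_targets(
    sets: Mapping[str, TargetSet | set],
    focal: str,
    exclude: Iterable[str],
) -> set[str]:
    """Targets of ``focal`` not predicted for any identifier in ``exclude``.

    This is the unique-target exclusion used to isolate isomiR-specific
    repertoires (e.g. removing 3p.1 and 5p targets from the 3p.2 set).
    """

    def genes_of(key: str) -> set[str]:
        if key not in sets:
            raise KeyError(f"unknown target-set identifier {key!r}")
        val = sets[key]
        return set(val.genes) if isinstance(val, TargetSet) else set(val)

    result = genes_of(focal)
    for other in exclude:
        result -= genes_of(other)
    return result
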