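"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions this pipeline targets: a
cartilage-style small-RNA read pool dominated by 3'-modified and mixed
isomiRs of one hairpin arm, UTRomes with planted seed-match sites, DE tables
in which planted targets are repressed with Gaussian noise, and multi-study
compendia in which the mean target fold change is negatively coupled to a
designated host gene's fold change.

All generators are bit-reproducible given (spec, rng_seed); every manifest
records the seed used.  Background UTR sequence is uniform over A/C/G/U with
rejection of accidental planted-motif occurrences, so truth tables are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import normalize_rna
from .catalog import Alignment, classify_isomir
from .sites import SITE_TYPES, SiteMotifSet, scan_utr, site_motifs

_NTS = np.array(list("ACGU"))


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NTS, size=length))


# ---------------------------------------------------------------------------
# Locus and read pools
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatureAnnotation:
    arm: str
    start: int
    length: int


@dataclass
class LocusSpec:
    """A miRNA hairpin with genomic flanks and two mature annotations."""

    hairpin_name: str
    hairpin_seq: str
    flank5: str
    flank3: str
    mature_annotations: list[MatureAnnotation]

    def __post_init__(self) -> None:
        self.hairpin_seq = normalize_rna(self.hairpin_seq)
        self.flank5 = normalize_rna(self.flank5)
        self.flank3 = normalize_rna(self.flank3)
        if len(self.flank5) < 10 or len(self.flank3) < 10:
            raise ValueError("flanks must be >= 10 nt each")
        spans = []
        for ann in self.mature_annotations:
            if ann.arm not in ("5p", "3p"):
                raise ValueError(f"arm must be 5p/3p, got {ann.arm!r}")
            if ann.start < 0 or ann.start + ann.length > len(self.hairpin_seq):
                raise ValueError("mature interval outside hairpin")
            spans.append((ann.start, ann.start + ann.length))
        spans.sort()
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("mature arms overlap")

    @property
    def context(self) -> str:
        return self.flank5 + self.hairpin_seq + self.flank3

    def mature(self, arm: str) -> MatureAnnotation:
        for ann in self.mature_annotations:
            if ann.arm == arm:
                return ann
        raise KeyError(f"no {arm} mature annotation")

    def mature_seq(self, arm: str) -> str:
        ann = self.mature(arm)
        return self.hairpin_seq[ann.start : ann.start + ann.length]


def gen_locus(rng_seed: int, hairpin_length: int = 110, mature_length: int = 22) -> LocusSpec:
    """A random hairpin locus with one 5p and one 3p mature annotation.

    Deterministic for a fixed seed.  Raises when the hairpin cannot hold two
    disjoint matures plus a loop (hairpin_length < 2*mature_length + 10).
    """
    if hairpin_length < 2 * mature_length + 10:
        raise ValueError(
            f"hairpin_length {hairpin_length} < 2*{mature_length} + 10; "
            "cannot place two disjoint mature arms"
        )
    rng = np.random.default_rng(rng_seed)
    hairpin = _random_rna(rng, hairpin_length)
    start_5p = 3
    start_3p = hairpin_length - mature_length - 3
    return LocusSpec(
        hairpin_name=f"syn-mir-{rng_seed}",
        hairpin_seq=hairpin,
        flank5=_random_rna(rng, 10),
        flank3=_random_rna(rng, 10),
        mature_annotations=[
            MatureAnnotation("5p", start_5p, mature_length),
            MatureAnnotation("3p", start_3p, mature_length),
        ],
    )


@dataclass(frozen=True)
class IsomiRComposition:
    """One mixture component of a read pool."""

    five_prime_offset: int
    three_prime_templated: int
    nontemplated_tail: str
    weight: float


@dataclass
class ReadCompositionSpec:
    """Mixture of isomiR species plus a per-read extra 3'-A rate."""

    entries: list[IsomiRComposition]
    total_depth: int
    tail_A_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.total_depth <= 0:
            raise ValueError("total_depth must be > 0")
        total = sum(e.weight for e in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if not 0.0 <= self.tail_A_rate <= 1.0:
            raise ValueError("tail_A_rate must be in [0, 1]")


def default_read_composition(total_depth: int = 100_000) -> ReadCompositionSpec:
    """A cartilage-like miR-140-3p mixture: ~5% canonical reads, ~25%
    perfectly templated overall, the rest carrying nontemplated tails that
    are predominantly adenines, and two 5' registers (0 and -1) so the pool
    carries exactly two seed heptamers."""
    entries = [
        IsomiRComposition(0, 0, "", 0.05),     # canonical
        IsomiRComposition(0, 1, "", 0.07),     # templated 3' extension
        IsomiRComposition(0, -1, "", 0.05),    # templated 3' trim
        IsomiRComposition(-1, 1, "", 0.09),    # mixed, templated
        IsomiRComposition(0, 0, "A", 0.25),    # 3' A tail
        IsomiRComposition(-1, 0, "A", 0.20),   # mixed with A tail
        IsomiRComposition(0, 1, "A", 0.10),
        IsomiRComposition(-1, 1, "A", 0.09),
        IsomiRComposition(0, 0, "U", 0.05),    # minor U tails
        IsomiRComposition(-1, 0, "U", 0.05),
    ]
    return ReadCompositionSpec(entries=entries, total_depth=total_depth, tail_A_rate=0.05)


def _canonical_decomposition(
    read: str, ctx: str, read_start: int, mature_end: int
) -> tuple[int, str]:
    """Greedy longest-templated-extension decomposition of a constructed read.

    Returns (three_prime_offset, nontemplated_tail) under the same
    templated-first convention the catalog uses for classification.
    """
    i = 0
    limit = min(len(read), len(ctx) - read_start)
    while i < limit and read[i] == ctx[read_start + i]:
        i += 1
    return (read_start + i) - mature_end, read[i:]


def gen_read_pool(
    locus: LocusSpec,
    spec: ReadCompositionSpec,
    rng_seed: int,
    arm: str = "3p",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial read pool for one mature arm, with a truth manifest.

    Returns ``(pool, manifest)``: the pool has columns (sequence, count);
    the manifest adds the true 5'/3' offsets, nontemplated tail, templated
    flag and category per distinct sequence.  Truth is recorded in canonical
    (greedy templated-first) form, so a constructed tail that happens to
    match the genomic continuation is reported as a templated extension.
    """
    rng = np.random.default_rng(rng_seed)
    ann = locus.mature(arm)
    ctx = locus.context
    ms = len(locus.flank5) + ann.start
    me = ms + ann.length

    # build each component's sequence, with and without the extra 3' A
    weights = np.array([e.weight for e in spec.entries])
    counts = rng.multinomial(spec.total_depth, weights / weights.sum())

    rows: list[tuple[str, int, int, int, str]] = []
    for entry, n in zip(spec.entries, counts):
        if n == 0:
            continue
        read_start = ms - entry.five_prime_offset
        read_end = me + entry.three_prime_templated
        if read_start < 0 or read_end > len(ctx) or read_start >= read_end:
            raise ValueError(
                f"offsets ({entry.five_prime_offset}, {entry.three_prime_templated}) "
                "escape the templated context"
            )
        tail = normalize_rna(entry.nontemplated_tail) if entry.nontemplated_tail else ""
        base = ctx[read_start:read_end] + tail
        n_extra_a = rng.binomial(n, spec.tail_A_rate) if spec.tail_A_rate > 0 else 0
        for seq, cnt in ((base, n - n_extra_a), (base + "A", n_extra_a)):
            if cnt == 0:
                continue
            tpo, nt_tail = _canonical_decomposition(seq, ctx, read_start, me)
            rows.append((seq, cnt, entry.five_prime_offset, tpo, nt_tail))

    df = pd.DataFrame(rows, columns=["sequence", "count", "five_prime_offset", "three_prime_offset", "nontemplated_tail"])
    # distinct components can collapse onto one sequence (e.g. a trimmed read
    # regaining its base via the A-tail); truth must then agree
    grouped = df.groupby("sequence", sort=True)
    manifest_rows = []
    for seq, grp in grouped:
        truths = grp[["five_prime_offset", "three_prime_offset", "nontemplated_tail"]].drop_duplicates()
        if len(truths) > 1:
            raise RuntimeError(f"inconsistent truth for collapsed sequence {seq}")
        fpo = int(grp["five_prime_offset"].iloc[0])
        tpo = int(grp["three_prime_offset"].iloc[0])
        tail = str(grp["nontemplated_tail"].iloc[0])
        category, templated = classify_isomir(Alignment(fpo, tpo, tail))
        manifest_rows.append(
            {
                "sequence": seq,
                "count": int(grp["count"].sum()),
                "five_prime_offset": fpo,
                "three_prime_offset": tpo,
                "nontemplated_tail": tail,
                "templated": templated,
                "category": category,
                "rng_seed": rng_seed,
            }
        )
    manifest = pd.DataFrame(manifest_rows).sort_values("sequence").reset_index(drop=True)
    pool = manifest[["sequence", "count"]].copy()
    return pool, manifest


# ---------------------------------------------------------------------------
# UTRomes with planted target sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTargetTruth:
    """Request/record of one seed-match site planted in one gene's UTR.

    ``utr_position`` is the 0-based offset of the planted motif string
    (which for 7mer-m8/8mer begins one nt 5' of the 6mer core).
    """

    gene: str
    planted_isomir: str
    site_type: str
    utr_position: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"site_type must be one of {SITE_TYPES}")


def _motif_for(motifs: SiteMotifSet, site_type: str) -> str:
    return {
        "6mer": motifs.six_mer,
        "7mer-A1": motifs.seven_a1,
        "7mer-m8": motifs.seven_m8,
        "8mer": motifs.eight_mer,
    }[site_type]


def _core_position(planted: PlantedTargetTruth) -> int:
    return planted.utr_position + (1 if planted.site_type in ("7mer-m8", "8mer") else 0)


def gen_utrome(
    n_genes: int,
    planting: Sequence[PlantedTargetTruth],
    mirna_seqs: Mapping[str, str],
    rng_seed: int,
    utr_length: int = 80,
    max_tries: int = 2000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random UTRome with the requested seed sites planted.

    Background sequence is uniform A/C/G/U, rejection-sampled so that every
    requested site appears at its requested position with its exact type and
    the background is otherwise seed-free: any remaining hit must overlap a
    planted window.  Overlapping-seed isomiRs (e.g. a -1-shifted pair, whose
    7mer-A1 site *is* the other's 7mer-m8 site) necessarily induce
    cross-hits inside planted windows; these are kept and recorded.  The
    truth table therefore lists every site hit in the emitted UTRome
    (gene, isomir, site_type, utr_position of the 6mer core), making
    downstream scans exactly checkable.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(rng_seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    motif_sets = {name: site_motifs(seq, isomir=name) for name, seq in mirna_seqs.items()}

    by_gene: dict[str, list[PlantedTargetTruth]] = {g: [] for g in genes}
    for p in planting:
        if p.gene not in by_gene:
            raise KeyError(f"planted gene {p.gene!r} not in the UTRome universe")
        if p.planted_isomir not in motif_sets:
            raise KeyError(f"no mature sequence given for isomiR {p.planted_isomir!r}")
        motif = _motif_for(motif_sets[p.planted_isomir], p.site_type)
        if p.utr_position < 0 or p.utr_position + len(motif) > utr_length:
            raise ValueError(
                f"motif {motif} does not fit at position {p.utr_position} "
                f"in a {utr_length}-nt UTR"
            )
        by_gene[p.gene].append(p)

    utrome: dict[str, str] = {}
    truth_rows: list[dict] = []
    for gene in genes:
        wanted = by_gene[gene]
        windows = [
            (
                p.utr_position,
                p.utr_position + len(_motif_for(motif_sets[p.planted_isomir], p.site_type)),
            )
            for p in wanted
        ]
        required = {
            (p.planted_isomir, _core_position(p), p.site_type) for p in wanted
        }
        for attempt in range(max_tries):
            seq = list(_random_rna(rng, utr_length))
            for p in wanted:
                motif = _motif_for(motif_sets[p.planted_isomir], p.site_type)
                seq[p.utr_position : p.utr_position + len(motif)] = motif
            candidate = "".join(seq)
            hits = {
                name: scan_utr(candidate, ms, gene) for name, ms in motif_sets.items()
            }
            found = {
                (name, h.position, h.site_type)
                for name, hlist in hits.items()
                for h in hlist
            }
            in_windows = all(
                any(h.position < end and h.position + 6 > start for start, end in windows)
                for hlist in hits.values()
                for h in hlist
            )
            if required <= found and in_windows:
                utrome[gene] = candidate
                truth_rows.extend(
                    {
                        "gene": gene,
                        "isomir": name,
                        "site_type": h.site_type,
                        "utr_position": h.position,
                    }
                    for name, hlist in sorted(hits.items())
                    for h in hlist
                )
                break
        else:
            raise RuntimeError(f"could not plant sites in gene {gene} after {max_tries} tries")

    truth = pd.DataFrame(
        truth_rows, columns=["gene", "isomir", "site_type", "utr_position"]
    )
    return utrome, truth


# ---------------------------------------------------------------------------
# DE tables and compendia
# ---------------------------------------------------------------------------

def gen_de_table(
    truth_targets: set[str],
    effect_delta: float,
    noise_sd: float,
    n_genes: int,
    rng_seed: int,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """DE table with planted repression of a target set.

    Non-targets draw log2fc ~ N(0, noise_sd^2); targets ~ N(-effect_delta,
    noise_sd^2).  Adjusted P-values are Benjamini-Hochberg corrected
    two-sided z-test P-values under the null N(0, noise_sd^2).
    """
    if not np.isfinite(effect_delta):
        raise ValueError("effect_delta must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if genes is None:
        genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    genes = list(genes)
    unknown = set(truth_targets) - set(genes)
    if unknown:
        raise KeyError(f"targets outside the gene universe, e.g. {sorted(unknown)[:5]}")
    rng = np.random.default_rng(rng_seed)
    is_target = np.array([g in truth_targets for g in genes])
    log2fc = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else np.zeros(len(genes))
    log2fc = log2fc - effect_delta * is_target
    if noise_sd > 0:
        pvals = 2.0 * stats.norm.sf(np.abs(log2fc) / noise_sd)
    else:
        pvals = np.where(log2fc != 0, 0.0, 1.0)
    adj_p = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({"gene": genes, "log2fc": log2fc, "adj_p": adj_p})


@dataclass
class CompendiumSpec:
    """Conditions for a multi-study compendium with host-target coupling.

    ``coupling_beta`` is the planted slope of the per-study mean target
    log2FC on the host gene's log2FC (negative for genuine repression);
    ``noise_sd`` is the per-gene Gaussian noise.  ``host_sig_fraction``
    controls how many studies carry a significant host-gene change (the
    remainder get a non-significant host row, for filtering tests).
    """

    n_studies: int = 124
    host_gene: str = "WWP2"
    coupling_beta: float = -0.4
    noise_sd: float = 0.1
    n_genes: int = 1000
    target_fraction: float = 0.1
    rng_seed: int = 0
    host_fc_range: float = 2.0
    host_sig_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_studies < 2:
            raise ValueError("n_studies must be >= 2")
        if not 0 < self.target_fraction < 1:
            raise ValueError("target_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_compendium(spec: CompendiumSpec) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-study DE tables whose mean target shift tracks the host gene.

    Host log2FC is drawn uniformly over a symmetric range; each study's
    targets are shifted by coupling_beta * host_fc plus per-gene noise.
    The manifest records the planted beta, the fixed target list, and each
    study's host fold change and significance flag.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    n_targets = max(1, round(spec.target_fraction * spec.n_genes))
    targets = set(rng.choice(genes, size=n_targets, replace=False))

    host_fcs = rng.uniform(-spec.host_fc_range, spec.host_fc_range, size=spec.n_studies)
    sig_flags = rng.random(spec.n_studies) < spec.host_sig_fraction

    studies: dict[str, pd.DataFrame] = {}
    manifest_studies = []
    for i, (host_fc, sig) in enumerate(zip(host_fcs, sig_flags)):
        study_id = f"study{i + 1:03d}"
        study_seed = int(rng.integers(0, 2**31 - 1))
        de = gen_de_table(
            truth_targets=targets,
            effect_delta=-spec.coupling_beta * host_fc,
            noise_sd=spec.noise_sd,
            n_genes=spec.n_genes,
            rng_seed=study_seed,
            genes=genes,
        )
        host_adj_p = 1e-8 if sig else 0.5
        host_row = pd.DataFrame(
            {"gene": [spec.host_gene], "log2fc": [host_fc], "adj_p": [host_adj_p]}
        )
        studies[study_id] = pd.concat([de, host_row], ignore_index=True)
        manifest_studies.append(
            {
                "study_id": study_id,
                "host_log2fc": float(host_fc),
                "host_significant": bool(sig),
                "rng_seed": study_seed,
            }
        )

    manifest = {
        "host_gene": spec.host_gene,
        "coupling_beta": spec.coupling_beta,
        "noise_sd": spec.noise_sd,
        "targets": sorted(targets),
        "rng_seed": spec.rng_seed,
        "studies": manifest_studies,
    }
    return studies, manifest
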