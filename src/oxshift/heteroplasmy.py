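"""Heteroplasmy call processing: dual-run merging, quality filtering,
private/shared classification, consequence annotation, burden summaries and
the gene-size correlation.

A heteroplasmy (HP) is a position where mutant and wild-type mtDNA molecules
coexist; the HP level is the mutant allele fraction (VAF).  Samples are
sequenced in two independent runs and only variants observed in both runs
are kept, at the mean of the two VAFs.  Detection thresholds follow the
standard deep-sequencing practice for mtDNA: a minimum VAF (default 2%),
per-strand coverage, and forward/reverse VAF agreement (strand bias).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mtgenome import GeneModel, VariantConsequence, annotate_variant

__all__ = [
    "HeteroplasmyCall",
    "HeteroplasmyRecord",
    "DELETERIOUS_GENES",
    "merge_runs",
    "filter_calls",
    "classify_private_shared",
    "classify_consequence",
    "flag_deleterious",
    "burden_and_strata",
    "mutpred_bins",
    "nd_gene_size_correlation",
]

#: Non-synonymous variants in these genes (Complex I, Complex IV and the
#: Complex III subunit cytochrome b) are treated as potentially deleterious
#: for OXPHOS assembly/function; ATP-synthase genes are excluded.
DELETERIOUS_GENES = frozenset(
    {f"MT-ND{i}" for i in range(1, 7)}
    | {"MT-ND4L"}
    | {f"MT-CO{i}" for i in range(1, 4)}
    | {"MT-CYB"}
)

CI_GENES = frozenset({f"MT-ND{i}" for i in range(1, 7)} | {"MT-ND4L"})

#: AF strata of per-variant heteroplasmy level: left-closed/right-open except
#: the last bin, so a level of exactly 0.10 falls in "10-20%".
AF_BINS = ((0.0, 0.10), (0.10, 0.20), (0.20, 0.50), (0.50, 1.0 + 1e-12))
AF_BIN_LABELS = ("<10%", "10-20%", "20-50%", ">50%")


@dataclass(frozen=True)
class HeteroplasmyCall:
    """One per-run variant observation."""

    patient_id: str
    sample_id: str
    tissue: Literal["benign", "malignant"]
    run_id: str
    pos: int
    ref: str
    alt: str
    vaf: float
    fwd_cov: int
    rev_cov: int
    fwd_alt: int
    rev_alt: int
    mutpred: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF out of [0,1]: {self.vaf}")
        if not (1 <= self.pos <= 16569):
            raise ValueError(f"position out of rCRS range: {self.pos}")
        if self.fwd_alt > self.fwd_cov or self.rev_alt > self.rev_cov:
            raise ValueError("alt reads exceed strand coverage")


@dataclass
class HeteroplasmyRecord:
    """A dual-run-confirmed variant in one sample."""

    patient_id: str
    sample_id: str
    tissue: Literal["benign", "malignant"]
    pos: int
    ref: str
    alt: str
    hp_level: float  # mean VAF across runs
    fwd_cov: int
    rev_cov: int
    fwd_alt: int
    rev_alt: int
    mutpred: Optional[float] = None
    consequences: list[VariantConsequence] = field(default_factory=list)
    privacy: Optional[Literal["private_benign", "private_cancer", "shared"]] = None
    deleterious: Optional[bool] = None
    is_homoplasmic: bool = False

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)

    @property
    def synonymy(self) -> Optional[str]:
        if not self.consequences:
            return None
        kinds = [c.synonymy for c in self.consequences]
        # a variant overlapping two protein genes is non-synonymous if it is
        # non-synonymous in either frame
        if "non_synonymous" in kinds:
            return "non_synonymous"
        return kinds[0]

    @property
    def genes(self) -> list[str]:
        return [c.gene for c in self.consequences]


def merge_runs(calls: Sequence[HeteroplasmyCall]) -> tuple[
    list[HeteroplasmyRecord], dict
]:
    """Merge per-run calls into dual-run-confirmed records.

    A variant is kept only when observed in (at least) two different runs of
    the same sample; its heteroplasmy level is the mean VAF across runs.
    Strand counts are summed across runs.  Returns the records plus a report
    with the number of single-run variants dropped per sample.

    Raises if any sample was sequenced in fewer than two runs.
    """
    runs_per_sample: dict[str, set] = defaultdict(set)
    for c in calls:
        runs_per_sample[c.sample_id].add(c.run_id)
    single = [s for s, r in sorted(runs_per_sample.items()) if len(r) < 2]
    if single:
        raise ValueError(f"samples with a single sequencing run: {single}")

    grouped: dict[tuple, list[HeteroplasmyCall]] = defaultdict(list)
    for c in calls:
        grouped[(c.sample_id, c.pos, c.ref, c.alt)].append(c)

    records: list[HeteroplasmyRecord] = []
    dropped: dict[str, int] = defaultdict(int)
    for (sample_id, pos, ref, alt), obs in sorted(grouped.items()):
        runs = {c.run_id for c in obs}
        if len(runs) < 2:
            dropped[sample_id] += 1
            continue
        first = obs[0]
        records.append(
            HeteroplasmyRecord(
                patient_id=first.patient_id,
                sample_id=sample_id,
                tissue=first.tissue,
                pos=pos,
                ref=ref,
                alt=alt,
                hp_level=float(np.mean([c.vaf for c in obs])),
                fwd_cov=sum(c.fwd_cov for c in obs),
                rev_cov=sum(c.rev_cov for c in obs),
                fwd_alt=sum(c.fwd_alt for c in obs),
                rev_alt=sum(c.rev_alt for c in obs),
                mutpred=first.mutpred,
            )
        )
    return records, {"single_run_dropped": dict(dropped)}


def _strand_tolerance(rec: HeteroplasmyRecord, floor: float = 0.1) -> float:
    """Default strand-agreement tolerance: max(floor, 3 binomial SDs)."""
    n = min(rec.fwd_cov, rec.rev_cov)
    if n == 0:
        return floor
    p = rec.hp_level
    return max(floor, 3.0 * math.sqrt(p * (1.0 - p) / n))


def filter_calls(
    records: Sequence[HeteroplasmyRecord],
    min_vaf: float = 0.02,
    min_strand_cov: int = 10,
    strand_tolerance: Optional[float] = None,
    homoplasmy_cut: float = 0.95,
) -> tuple[list[HeteroplasmyRecord], list[dict]]:
    """Apply detection filters; returns (kept records, rejection log).

    Keeps records with ``hp_level > min_vaf``, both strand coverages
    ``> min_strand_cov`` and forward/reverse VAF difference within the strand
    tolerance (default adaptive: ``max(0.1, 3 binomial SD)``; pass a number
    to fix it, or ``float('inf')`` to disable).  Records at or above
    ``homoplasmy_cut`` are kept but labelled homoplasmic; burden summaries
    exclude them from heteroplasmy counts.
    """
    if not (0.0 < min_vaf < 1.0):
        raise ValueError("min_vaf must be in (0, 1)")
    if min_strand_cov < 0:
        raise ValueError("min_strand_cov must be non-negative")
    kept: list[HeteroplasmyRecord] = []
    log: list[dict] = []

    def reject(rec, reason):
        log.append(
            {"sample_id": rec.sample_id, "pos": rec.pos, "ref": rec.ref,
             "alt": rec.alt, "reason": reason}
        )

    for rec in records:
        if rec.hp_level <= min_vaf:
            reject(rec, f"hp_level {rec.hp_level:.4f} <= threshold {min_vaf}")
            continue
        if rec.fwd_cov <= min_strand_cov or rec.rev_cov <= min_strand_cov:
            reject(rec, f"strand coverage {rec.fwd_cov}/{rec.rev_cov} <= "
                        f"{min_strand_cov}")
            continue
        fwd_vaf = rec.fwd_alt / rec.fwd_cov if rec.fwd_cov else 0.0
        rev_vaf = rec.rev_alt / rec.rev_cov if rec.rev_cov else 0.0
        tol = strand_tolerance if strand_tolerance is not None \
            else _strand_tolerance(rec)
        if abs(fwd_vaf - rev_vaf) > tol:
            reject(rec, f"strand bias |{fwd_vaf:.3f} - {rev_vaf:.3f}| > "
                        f"{tol:.3f}")
            continue
        kept.append(replace(rec, is_homoplasmic=rec.hp_level >= homoplasmy_cut))
    return kept, log


def classify_private_shared(
    records: Sequence[HeteroplasmyRecord],
) -> list[HeteroplasmyRecord]:
    """Set the privacy field: a variant key present in both tissues of a
    patient is shared; otherwise private to the tissue where it occurs.

    Every patient must contribute both a benign and a malignant sample (a
    sample with zero variants still counts as present if any record of the
    patient exists; patients entirely absent cannot be checked here and are
    validated at the I/O layer)."""
    by_patient: dict[str, list[HeteroplasmyRecord]] = defaultdict(list)
    for r in records:
        by_patient[r.patient_id].append(r)
    out: list[HeteroplasmyRecord] = []
    for patient, recs in sorted(by_patient.items()):
        keys = {"benign": set(), "malignant": set()}
        for r in recs:
            keys[r.tissue].add(r.key)
        shared = keys["benign"] & keys["malignant"]
        for r in recs:
            if r.key in shared:
                privacy = "shared"
            elif r.tissue == "benign":
                privacy = "private_benign"
            else:
                privacy = "private_cancer"
            out.append(replace(r, privacy=privacy))
    return out


def classify_consequence(
    records: Sequence[HeteroplasmyRecord], model: GeneModel
) -> list[HeteroplasmyRecord]:
    """Annotate each record with codon-level consequences (see
    :func:`oxshift.mtgenome.annotate_variant`)."""
    return [
        replace(r, consequences=annotate_variant(r.pos, r.ref, r.alt, model))
        for r in records
    ]


def flag_deleterious(
    records: Sequence[HeteroplasmyRecord],
) -> list[HeteroplasmyRecord]:
    """Potentially deleterious = non-synonymous AND in an MT-ND, MT-CO or
    MT-CYB gene (ATP-synthase genes excluded)."""
    out = []
    for r in records:
        deleterious = any(
            c.synonymy == "non_synonymous" and c.gene in DELETERIOUS_GENES
            for c in r.consequences
        )
        out.append(replace(r, deleterious=deleterious))
    return out


def _af_bin(level: float) -> str:
    for (lo, hi), lab in zip(AF_BINS, AF_BIN_LABELS):
        if lo <= level < hi:
            return lab
    raise ValueError(f"level out of range: {level}")


def burden_and_strata(
    records: Sequence[HeteroplasmyRecord],
    sample_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-sample burden summary.

    Columns: heteroplasmy count (homoplasmic records excluded), counts per
    AF stratum, the maximum heteroplasmy level among non-synonymous
    Complex I-gene variants, and the derived CI-level stratum
    (none / 30-60% / >60%).  ``sample_ids`` may add samples with no records
    so they appear with zero counts.
    """
    by_sample: dict[str, list[HeteroplasmyRecord]] = defaultdict(list)
    for r in records:
        by_sample[r.sample_id].append(r)
    if sample_ids is not None:
        for s in sample_ids:
            by_sample.setdefault(s, [])
    rows = []
    for sample, recs in sorted(by_sample.items()):
        hp = [r for r in recs if not r.is_homoplasmic]
        ci_nonsyn = [
            r.hp_level
            for r in hp
            if any(
                c.synonymy == "non_synonymous" and c.gene in CI_GENES
                for c in r.consequences
            )
        ]
        max_ci = max(ci_nonsyn) if ci_nonsyn else np.nan
        if not ci_nonsyn or max_ci < 0.30:
            stratum = "none"
        elif max_ci <= 0.60:
            stratum = "30-60%"
        else:
            stratum = ">60%"
        row = {
            "sample_id": sample,
            "patient_id": recs[0].patient_id if recs else "",
            "tissue": recs[0].tissue if recs else "",
            "hp_count": len(hp),
            "max_ci_nonsyn_level": max_ci,
            "ci_level_stratum": stratum,
        }
        for lab in AF_BIN_LABELS:
            row[f"n_af_{lab}"] = sum(1 for r in hp if _af_bin(r.hp_level) == lab)
        rows.append(row)
    return pd.DataFrame(rows)


def mutpred_bins(
    records: Sequence[HeteroplasmyRecord], high_cut: float = 0.75
) -> pd.DataFrame:
    """Per-tissue proportion of non-synonymous HPs with a high MutPred
    pathogenicity score (> ``high_cut``); unscored records counted as ``na``."""
    rows = []
    for tissue in ("benign", "malignant"):
        nonsyn = [
            r for r in records
            if r.tissue == tissue and r.synonymy == "non_synonymous"
        ]
        scored = [r for r in nonsyn if r.mutpred is not None]
        n_high = sum(1 for r in scored if r.mutpred > high_cut)
        rows.append(
            {
                "tissue": tissue,
                "n_nonsyn": len(nonsyn),
                "n_scored": len(scored),
                "n_na": len(nonsyn) - len(scored),
                "prop_high": n_high / len(scored) if scored else np.nan,
            }
        )
    return pd.DataFrame(rows)


def nd_gene_size_correlation(
    records: Sequence[HeteroplasmyRecord],
    model: GeneModel,
    tissue: str = "malignant",
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of per-gene HP count with gene length (kbp) for
    the seven MT-ND genes in the given tissue.

    The p-value is the two-tailed t-test on n-2 degrees of freedom.  A strong
    correlation indicates mutations land roughly uniformly per base, i.e. no
    positional hotspots.
    """
    nd_genes = [g for g in sorted(CI_GENES) if g in model]
    if len(nd_genes) < 3:
        raise ValueError("need at least 3 MT-ND genes in the model")
    counts = {g: 0 for g in nd_genes}
    for r in records:
        if r.tissue != tissue:
            continue
        for g in set(r.genes):
            if g in counts:
                counts[g] += 1
    table = pd.DataFrame(
        {
            "gene": nd_genes,
            "length_kbp": [model[g].length / 1000.0 for g in nd_genes],
            "hp_count": [counts[g] for g in nd_genes],
        }
    )
    r, p = stats.pearsonr(table["length_kbp"], table["hp_count"])
    return float(r), float(p), table
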