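"""Seeded generators for synthetic study data.

Each generator emulates one input of the analysis with the statistical
structure the pipeline assumes, and returns the dataset together with a
truth record, so every downstream stage can be tested end to end without
access to the original cohort:

* paired benign/malignant SUIT respirometry tables with a programmable
  N->S substrate shift (benign > tumor GM-pathway capacity, tumor > benign
  succinate effect, amplified in the high-grade stratum), optionally with
  synthetic titration traces;
* dual-run heteroplasmy call tables with a beta allele-frequency spectrum,
  binomial per-strand read counts, run-to-run VAF jitter and optional
  spike-in of known worked variants;
* duplex qPCR Cq tables derived from true copy numbers;
* expression + survival cohorts in which a latent severe phenotype shifts a
  planted metagene set and scales the hazard.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mtgenome import GeneModel
from .respirometry import SUIT_STATES, SuitStateTable, TitrationTrace
from .copynumber import QpcrMeasurement

__all__ = [
    "RespirometrySpec",
    "HeteroplasmySpec",
    "QpcrSpec",
    "ExpressionSurvivalSpec",
    "gen_respirometry_cohort",
    "gen_heteroplasmy_tables",
    "gen_qpcr",
    "gen_expression_survival",
    "SPIKE_IN_VARIANTS",
]

#: Worked variants with known consequences, available for spike-in:
#: (pos, ref, alt, expected protein change, gene)
SPIKE_IN_VARIANTS = (
    (11991, "T", "C", "MT-ND4", "F411S"),
    (13495, "A", "G", "MT-ND5", "T387A"),
    (10551, "T", "C", "MT-ND4L", "S28P"),
)

# Mean mass-specific O2 fluxes (pmol s^-1 mg^-1) per SUIT state.  The deltas
# between consecutive states reproduce the cohort-level effects of the study
# conditions: ADP effect 4.5 (benign) vs 2.4 (tumor), oxidative-stress drop
# 1.1 vs 1.7, larger pyruvate and succinate gains in tumors, full convergent
# capacity (NS) restored in tumors, and a smaller rotenone-sensitive
# (N-pathway) share in tumors.  The tumor GM_P/NS_E ratio centers near 0.27.
BENIGN_MEANS = {
    "GM_L": 2.4, "GM_P_pre": 6.9, "GM_P": 5.8, "N_P": 7.3, "NS_P": 13.0,
    "NS_E": 15.5, "S_E": 8.5, "ROX": 0.5,
}
TUMOR_MEANS = {
    "GM_L": 2.2, "GM_P_pre": 5.7, "GM_P": 4.0, "N_P": 6.0, "NS_P": 13.5,
    "NS_E": 15.0, "S_E": 10.0, "ROX": 0.5,
}
#: additional shift applied to high-grade (Gleason > 7) tumors
HIGH_GRADE_SHIFT = {"GM_P_pre": -1.5, "GM_P": -1.3, "N_P": -1.0, "S_E": 1.0}


@dataclass(frozen=True)
class RespirometrySpec:
    n_pairs: int = 50
    high_grade_fraction: float = 0.2
    benign_means: dict = field(default_factory=lambda: dict(BENIGN_MEANS))
    tumor_means: dict = field(default_factory=lambda: dict(TUMOR_MEANS))
    high_grade_shift: dict = field(default_factory=lambda: dict(HIGH_GRADE_SHIFT))
    between_subject_sd: float = 2.0  # common scale factor spread
    within_state_sd: float = 1.0  # residual per-state noise
    seed: int = 0

    def validate(self):
        bad = []
        if self.n_pairs < 1:
            bad.append("n_pairs")
        if not (0 <= self.high_grade_fraction <= 1):
            bad.append("high_grade_fraction")
        if self.between_subject_sd < 0:
            bad.append("between_subject_sd")
        if self.within_state_sd < 0:
            bad.append("within_state_sd")
        if bad:
            raise ValueError(f"invalid respirometry spec fields: {bad}")


def gen_respirometry_cohort(
    spec: RespirometrySpec = RespirometrySpec(),
    with_traces: bool = False,
) -> dict:
    """Generate a paired benign/malignant respirometry cohort.

    Subject-level variation is a shared multiplicative factor (tissue quality
    / mitochondrial density affects all states of a biopsy together) plus
    additive per-state noise.  Returns ``{"benign": [...], "malignant": [...],
    "truth": DataFrame, "gleason": [...]}`` and optionally per-sample traces.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    benign, malignant, truths, traces = [], [], [], {}
    n_high = int(round(spec.high_grade_fraction * spec.n_pairs))
    gleason = np.array([9] * n_high + [7] * (spec.n_pairs - n_high))
    rng.shuffle(gleason)
    for i in range(spec.n_pairs):
        pid = f"P{i+1:03d}"
        subj = 1.0 + rng.normal(0.0, spec.between_subject_sd / 15.0)
        subj = max(subj, 0.3)
        for tissue in ("benign", "malignant"):
            means = dict(
                spec.benign_means if tissue == "benign" else spec.tumor_means
            )
            if tissue == "malignant" and gleason[i] > 7:
                for k, v in spec.high_grade_shift.items():
                    means[k] = means[k] + v
            flux = {}
            for state, mu in means.items():
                noise = rng.normal(0.0, spec.within_state_sd)
                flux[state] = max(mu * subj + noise, 0.05)
            table = SuitStateTable(
                sample_id=f"{pid}_{'BE' if tissue == 'benign' else 'CA'}",
                tissue=tissue,
                flux=flux,
                wet_mass_mg=float(np.round(rng.normal(6.5, 1.5), 2)),
                replicate_ids=[f"{pid}_{tissue}_r1"],
            )
            (benign if tissue == "benign" else malignant).append(table)
            truths.append({"patient_id": pid, "tissue": tissue,
                           "gleason": int(gleason[i]), "subject_factor": subj,
                           **{f"true_{k}": v * subj for k, v in means.items()}})
            if with_traces:
                traces[table.sample_id] = _trace_from_states(
                    table, rng, chamber_volume_mL=2.0
                )
    out = {
        "benign": benign,
        "malignant": malignant,
        "gleason": gleason.tolist(),
        "truth": pd.DataFrame(truths),
    }
    if with_traces:
        out["traces"] = traces
    return out


def _trace_from_states(
    table: SuitStateTable,
    rng: np.random.Generator,
    state_duration_s: float = 180.0,
    sample_interval_s: float = 2.0,
    rel_noise: float = 0.01,
    chamber_volume_mL: float = 2.0,
) -> TitrationTrace:
    """Synthesize a titration trace whose plateaus encode the table's fluxes."""
    states = [s for s in SUIT_STATES if s in table.flux]
    times, fluxes, events = [], [], []
    t = 0.0
    o2 = [250.0]
    for state in states:
        events.append((t, state))
        target = table.flux[state] * table.wet_mass_mg / chamber_volume_mL
        n = int(state_duration_s / sample_interval_s)
        for k in range(n):
            # exponential approach to the plateau after each titration
            frac = 1.0 - np.exp(-k / 8.0)
            v = target * frac + rng.normal(0.0, rel_noise * max(abs(target), 1.0))
            times.append(t)
            fluxes.append(v)
            t += sample_interval_s
    times = np.asarray(times)
    fluxes = np.asarray(fluxes)
    o2 = 250.0 - np.cumsum(fluxes) * sample_interval_s * 1e-3
    return TitrationTrace(
        time_s=times, o2_uM=o2, flux_pmol_s_mL=fluxes, events=events
    )


@dataclass(frozen=True)
class HeteroplasmySpec:
    """Expected per-sample HP counts follow the study cohort: 33 private
    benign, 84 private cancer and ~15 shared variant sites across 50 pairs."""

    n_pairs: int = 50
    mean_private_benign: float = 33 / 50
    mean_private_cancer: float = 84 / 50
    mean_shared: float = 15 / 50
    af_alpha: float = 0.3
    af_beta: float = 2.0
    min_vaf: float = 0.02
    per_strand_depth: int = 5000
    run_vaf_jitter_sd: float = 0.01
    spike_in: bool = False
    seed: int = 0

    def validate(self):
        if self.n_pairs < 1 or self.per_strand_depth < 1:
            raise ValueError("invalid heteroplasmy spec: sizes must be positive")
        if not (0 < self.min_vaf < 1):
            raise ValueError("invalid heteroplasmy spec: min_vaf")


def _sample_af(rng, spec) -> float:
    """Beta(af_alpha, af_beta) truncated below at the detection threshold:
    a preponderance of low-level HPs with a minority above 50%."""
    while True:
        v = rng.beta(spec.af_alpha, spec.af_beta)
        if spec.min_vaf < v < 0.95:
            return float(v)


def gen_heteroplasmy_tables(
    spec: HeteroplasmySpec,
    model: GeneModel,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a dual-run heteroplasmy call table.

    Positions are sampled uniformly over non-control bases (so per-gene HP
    counts scale with gene length and the gene-size correlation emerges);
    alt alleles uniformly among the three non-reference bases.  Each variant
    is reported in two runs with jittered VAFs and binomial per-strand read
    counts.  Returns ``(calls, truth)`` as DataFrames; ``calls`` has one row
    per variant per run.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq = model.sequence
    coding_pos = np.array(
        [p for p in range(1, len(seq) + 1)
         if not model.in_control_region(p) and seq[p - 1] != "N"]
    )
    rows, truth_rows = [], []

    def emit(pid, tissues, pos, ref, alt, af):
        for tissue in tissues:
            sample = f"{pid}_{'BE' if tissue == 'benign' else 'CA'}"
            for run in ("run1", "run2"):
                vaf = float(np.clip(af + rng.normal(0, spec.run_vaf_jitter_sd),
                                    1e-4, 1.0))
                fwd_cov = int(rng.poisson(spec.per_strand_depth))
                rev_cov = int(rng.poisson(spec.per_strand_depth))
                rows.append({
                    "patient_id": pid, "sample_id": sample, "tissue": tissue,
                    "run_id": run, "pos": int(pos), "ref": ref, "alt": alt,
                    "vaf": vaf,
                    "fwd_cov": fwd_cov, "rev_cov": rev_cov,
                    "fwd_alt": int(rng.binomial(fwd_cov, vaf)),
                    "rev_alt": int(rng.binomial(rev_cov, vaf)),
                })
            truth_rows.append({"patient_id": pid, "tissue": tissue,
                               "pos": int(pos), "ref": ref, "alt": alt,
                               "true_af": af,
                               "privacy": "shared" if len(tissues) == 2 else
                               ("private_benign" if tissue == "benign"
                                else "private_cancer")})

    bases = "ACGT"
    for i in range(spec.n_pairs):
        pid = f"P{i+1:03d}"
        for tissues, mean in (
            (("benign",), spec.mean_private_benign),
            (("malignant",), spec.mean_private_cancer),
            (("benign", "malignant"), spec.mean_shared),
        ):
            for _ in range(rng.poisson(mean)):
                pos = int(rng.choice(coding_pos))
                ref = seq[pos - 1]
                alt = rng.choice([b for b in bases if b != ref])
                emit(pid, tissues, pos, ref, str(alt), _sample_af(rng, spec))
    if spec.spike_in:
        for k, (pos, ref, alt, _gene, _aa) in enumerate(SPIKE_IN_VARIANTS):
            pid = f"P{(k % spec.n_pairs) + 1:03d}"
            emit(pid, ("malignant",), pos, ref, alt, 0.58)
    calls = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return calls, truth


@dataclass(frozen=True)
class QpcrSpec:
    """True copy numbers are log-normal around the cohort median (~310 per
    diploid cell, range ~170-700)."""

    n_samples: int = 50
    log_cn_mean: float = float(np.log(310.0))
    log_cn_sd: float = 0.35
    cq_noise_sd: float = 0.1
    efficiency_base: float = 2.0
    plasmid_cq_mt: float = 20.0
    plasmid_cq_n: float = 20.0
    nuclear_cq_mean: float = 28.0
    seed: int = 0


def gen_qpcr(spec: QpcrSpec = QpcrSpec()) -> tuple[list[QpcrMeasurement], pd.DataFrame]:
    """Generate duplex qPCR measurements from true copy numbers.

    The mitochondrial Cq is placed so that ``2 * E**(-ddCq)`` equals the true
    CN exactly before noise; independent Gaussian noise (sd
    ``cq_noise_sd`` cycles) is then added to each Cq."""
    rng = np.random.default_rng(spec.seed)
    E = spec.efficiency_base
    measurements, truth = [], []
    for i in range(spec.n_samples):
        cn = float(np.exp(rng.normal(spec.log_cn_mean, spec.log_cn_sd)))
        cq_n = rng.normal(spec.nuclear_cq_mean, 0.5)
        # CN = 2*E^-(dCq_sample - dCq_plasmid)  =>  dCq_sample = dCq_plasmid - log_E(CN/2)
        dcq = (spec.plasmid_cq_mt - spec.plasmid_cq_n) - np.log(cn / 2.0) / np.log(E)
        cq_mt = cq_n + dcq
        m = QpcrMeasurement(
            sample_id=f"S{i+1:03d}",
            cq_mt=float(cq_mt + rng.normal(0, spec.cq_noise_sd)),
            cq_n=float(cq_n + rng.normal(0, spec.cq_noise_sd)),
            plasmid_cq_mt=spec.plasmid_cq_mt,
            plasmid_cq_n=spec.plasmid_cq_n,
            efficiency_base=E,
        )
        measurements.append(m)
        truth.append({"sample_id": m.sample_id, "true_cn": cn})
    return measurements, pd.DataFrame(truth)


@dataclass(frozen=True)
class ExpressionSurvivalSpec:
    """Cohort with a latent severe respiratory phenotype driving a planted
    metagene set and the hazard.  Survival is exponential with group-specific
    rates; censoring is independent uniform."""

    n_subjects: int = 200
    n_genes: int = 500
    n_planted: int = 11
    severe_fraction: float = 0.5
    effect_size: float = 2.0  # log2 expression shift of planted genes in severe
    noise_sd: float = 1.0
    baseline_hazard: float = 0.02  # events per month in the mild group
    hr_mild_vs_severe: float = 0.5
    censor_uniform_max: float = 120.0  # months
    endpoint: str = "DFS"
    seed: int = 0

    def validate(self):
        if min(self.n_subjects, self.n_genes, self.n_planted) < 1:
            raise ValueError("sizes must be positive")
        if not (0 < self.severe_fraction < 1):
            raise ValueError("severe_fraction must be in (0,1)")
        if self.hr_mild_vs_severe <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard parameters must be positive")


def gen_expression_survival(spec: ExpressionSurvivalSpec) -> dict:
    """Generate an expression + survival cohort.

    Expression is log2-scale Gaussian noise; the first ``n_planted`` genes
    (``MG001``...) are shifted upward by ``effect_size`` in severe subjects.
    Severe subjects have hazard ``baseline_hazard / hr_mild_vs_severe``;
    the mild:severe hazard ratio is therefore ``hr_mild_vs_severe`` (< 1
    means mild subjects do better).  Returns dict with keys ``cohort``
    (:class:`~oxshift.signature.SurvivalCohort`), ``labels``, ``planted_genes``
    and ``truth``.
    """
    from .signature import SurvivalCohort

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_subjects, spec.n_genes
    # the severe phenotype is assigned by ranking a latent respiratory
    # capacity and splitting at the severe_fraction quantile, mirroring a
    # median dichotomization of GM capacity (exactly balanced at 0.5)
    latent_gm = rng.normal(0.0, 1.0, n)
    k = max(1, min(n - 1, int(round(spec.severe_fraction * n))))
    severe = np.zeros(n, dtype=bool)
    severe[np.argsort(latent_gm)[:k]] = True
    genes = [f"MG{i+1:03d}" for i in range(spec.n_planted)] + [
        f"G{i+1:04d}" for i in range(g - spec.n_planted)
    ]
    X = rng.normal(0.0, spec.noise_sd, size=(g, n))
    X[: spec.n_planted, severe] += spec.effect_size
    X = X + 8.0  # arbitrary log2 abundance offset
    subjects = [f"SUBJ{i+1:04d}" for i in range(n)]
    hazard = np.where(
        severe, spec.baseline_hazard / spec.hr_mild_vs_severe, spec.baseline_hazard
    )
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, spec.censor_uniform_max, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-3)
    expr = pd.DataFrame(X, index=genes, columns=subjects)
    cohort = SurvivalCohort(
        expression=expr,
        time=pd.Series(time, index=subjects),
        event=pd.Series(event, index=subjects),
        endpoint=spec.endpoint,
        is_log_transformed=True,
        name=f"synthetic-{spec.seed}",
    )
    return {
        "cohort": cohort,
        "labels": ["severe" if s else "mild" for s in severe],
        "planted_genes": genes[: spec.n_planted],
        "truth": pd.DataFrame(
            {"subject": subjects, "severe": severe, "time": time, "event": event}
        ),
    }
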