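"""High-resolution respirometry: SUIT state fluxes, ROX correction, flux
control ratios and substrate/stress/inhibitor effects.

The substrate-uncoupler-inhibitor titration (SUIT) protocol measures oxygen
flux of a permeabilized tissue sample through a fixed sequence of coupling /
pathway states:

========  =====================================================================
state     meaning
========  =====================================================================
GM_L      LEAK respiration with glutamate & malate (no ADP)
GM_P_pre  glutamate&malate OXPHOS capacity after ADP, before oxidative stress
GM_P      glutamate&malate OXPHOS capacity after the H2O2 stress step
N_P       N-pathway OXPHOS capacity (pyruvate added)
NS_P      convergent NADH+succinate OXPHOS capacity
NS_E      maximal noncoupled electron-transfer capacity (FCCP) — the internal
          reference state for flux control ratios
S_E       S-pathway ET capacity after Complex I inhibition by rotenone
ROX       residual oxygen consumption after CI+CII+CIII inhibition
CIV_raw   ascorbate+TMPD single-step Complex IV flux
CIV_azide chemical background of the CIV assay after azide
========  =====================================================================

Fluxes are mass-specific (pmol O2 s^-1 mg^-1 wet mass) for tissue, or per
10^6 cells for suspensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "SUIT_STATES",
    "SuitStateTable",
    "TitrationTrace",
    "ProtocolError",
    "extract_state_fluxes",
    "rox_correct",
    "average_splits",
    "flux_control_ratios",
    "substrate_effects",
    "civ_activity",
    "s_pathway_compensation",
]

SUIT_STATES = (
    "GM_L", "GM_P_pre", "GM_P", "N_P", "NS_P", "NS_E", "S_E", "ROX",
    "CIV_raw", "CIV_azide",
)

#: effect -> (minuend state, subtrahend state)
EFFECT_DEFINITIONS = {
    "ADP_effect": ("GM_P_pre", "GM_L"),
    "stress_effect": ("GM_P", "GM_P_pre"),
    "pyruvate_effect": ("N_P", "GM_P"),
    "succinate_effect": ("NS_P", "N_P"),
    "FCCP_effect": ("NS_E", "NS_P"),
    "rotenone_effect": ("NS_E", "S_E"),
}


class ProtocolError(ValueError):
    """A required titration event or protocol state is missing."""


@dataclass
class SuitStateTable:
    """Per-sample mass-specific O2 flux for each measured SUIT state."""

    sample_id: str
    tissue: Literal["benign", "malignant", "cell_line"]
    flux: dict[str, float]
    wet_mass_mg: Optional[float] = None
    cells_per_mL: Optional[float] = None
    replicate_ids: list[str] = field(default_factory=list)
    rox_corrected: bool = False
    negative_flux_states: list[str] = field(default_factory=list)
    plateau_cv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.flux) - set(SUIT_STATES)
        if unknown:
            raise ProtocolError(f"unknown SUIT states: {sorted(unknown)}")
        if self.wet_mass_mg is not None and self.wet_mass_mg <= 0:
            raise ValueError("wet_mass_mg must be positive")
        for s, v in self.flux.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite flux for state {s}")

    def __getitem__(self, state: str) -> float:
        return self.flux[state]


@dataclass
class TitrationTrace:
    """Raw oxygraph trace: time series of O2 concentration and volume-specific
    flux, plus labelled titration events."""

    time_s: np.ndarray
    o2_uM: np.ndarray
    flux_pmol_s_mL: np.ndarray
    events: list[tuple[float, str]]  # (time_s, state label reached)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.o2_uM = np.asarray(self.o2_uM, dtype=float)
        self.flux_pmol_s_mL = np.asarray(self.flux_pmol_s_mL, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("trace time must be strictly increasing")
        labels = [lab for _, lab in self.events]
        if len(labels) != len(set(labels)):
            raise ProtocolError("duplicate titration event labels")


def extract_state_fluxes(
    trace: TitrationTrace,
    sample_id: str,
    tissue: str,
    wet_mass_mg: float,
    window_s: float = 60.0,
    chamber_volume_mL: float = 2.0,
    states: Optional[Sequence[str]] = None,
) -> SuitStateTable:
    """Read plateau fluxes for each protocol state from a titration trace.

    The plateau statistic is the *median* volume-specific flux over the
    trailing ``window_s`` seconds of each state (i.e. just before the next
    titration), which is robust to titration spikes.  Mass-specific flux is
    ``median * chamber_volume_mL / wet_mass_mg``.  The per-state coefficient
    of variation over the window is reported in ``plateau_cv``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if wet_mass_mg <= 0:
        raise ValueError("wet_mass_mg must be positive")
    wanted = list(states) if states is not None else [lab for _, lab in trace.events]
    have = {lab: t for t, lab in trace.events}
    missing = [s for s in wanted if s not in have]
    if missing:
        raise ProtocolError(f"missing titration events for states: {missing}")

    order = sorted(trace.events)
    ends = {lab: None for _, lab in order}
    for (t0, lab), nxt in zip(order, order[1:] + [None]):
        ends[lab] = nxt[0] if nxt is not None else float(trace.time_s[-1])

    flux = {}
    cv = {}
    for lab in wanted:
        t_end = ends[lab]
        t_start = max(t_end - window_s, have[lab])
        mask = (trace.time_s >= t_start) & (trace.time_s <= t_end)
        if not np.any(mask):
            raise ProtocolError(f"no trace samples in plateau window of {lab}")
        seg = trace.flux_pmol_s_mL[mask]
        med = float(np.median(seg))
        flux[lab] = med * chamber_volume_mL / wet_mass_mg
        cv[lab] = float(np.std(seg) / abs(med)) if med != 0 else float("inf")
    return SuitStateTable(
        sample_id=sample_id,
        tissue=tissue,
        flux=flux,
        wet_mass_mg=wet_mass_mg,
        replicate_ids=[sample_id],
        plateau_cv=cv,
    )


def rox_correct(table: SuitStateTable) -> SuitStateTable:
    """Subtract residual oxygen consumption (ROX) from every state flux.

    ROX is measured after inhibition of Complexes I-III and represents
    non-mitochondrial oxygen consumption.  Corrected values that fall below
    zero are retained (clamping would bias downstream effect deltas) but the
    affected states are flagged in ``negative_flux_states``.
    """
    if "ROX" not in table.flux:
        raise ProtocolError(f"sample {table.sample_id}: ROX state missing")
    rox = table.flux["ROX"]
    corrected = {}
    negative = []
    for state, v in table.flux.items():
        if state in ("ROX", "CIV_raw", "CIV_azide"):
            corrected[state] = 0.0 if state == "ROX" else v
            continue
        c = v - rox
        corrected[state] = c
        if c < 0:
            negative.append(state)
    return replace(
        table, flux=corrected, rox_corrected=True, negative_flux_states=negative
    )


def average_splits(tables: Sequence[SuitStateTable]) -> SuitStateTable:
    """Average split measurements of one biopsy (per-state arithmetic mean)."""
    if not tables:
        raise ValueError("no replicates given")
    if len(tables) == 1:
        return tables[0]
    ref = set(tables[0].flux)
    for t in tables[1:]:
        if set(t.flux) != ref:
            raise ProtocolError(
                "replicates measured different state sets; difference: "
                f"{sorted(ref ^ set(t.flux))}"
            )
    flux = {s: float(np.mean([t.flux[s] for t in tables])) for s in ref}
    reps: list[str] = []
    for t in tables:
        reps.extend(t.replicate_ids or [t.sample_id])
    return replace(tables[0], flux=flux, replicate_ids=reps)


def flux_control_ratios(table: SuitStateTable) -> dict[str, float]:
    """Normalize every state flux to the internal reference state NS_E.

    FCR(NS_E) is exactly 1.  Requires NS_E > 0.
    """
    if "NS_E" not in table.flux:
        raise ProtocolError(f"sample {table.sample_id}: NS_E state missing")
    ref = table.flux["NS_E"]
    if ref <= 0:
        raise ValueError(
            f"sample {table.sample_id}: degenerate reference NS_E = {ref}"
        )
    fcr = {s: v / ref for s, v in table.flux.items() if s not in ("CIV_raw", "CIV_azide")}
    fcr["NS_E"] = 1.0
    return fcr


def substrate_effects(table: SuitStateTable) -> dict[str, Optional[float]]:
    """Substrate/stress/inhibitor effect deltas between consecutive states.

    Missing states make the corresponding delta ``None`` rather than raising,
    so partial protocols still yield the computable effects.
    """
    out: dict[str, Optional[float]] = {}
    for effect, (a, b) in EFFECT_DEFINITIONS.items():
        if a in table.flux and b in table.flux:
            out[effect] = table.flux[a] - table.flux[b]
        else:
            out[effect] = None
    return out


def civ_activity(raw: float, azide: float) -> tuple[float, bool]:
    """Complex IV single-step activity: ascorbate+TMPD flux minus the azide
    chemical background.  Returns ``(activity, negative_flag)``."""
    if not (np.isfinite(raw) and np.isfinite(azide)):
        raise ValueError("CIV fluxes must be finite")
    act = raw - azide
    return act, act < 0


def s_pathway_compensation(
    titration: Sequence[tuple[float, SuitStateTable]],
) -> list[tuple[float, float]]:
    """Rotenone-titration compensation curve for cell lines.

    For each rotenone dose the rotenone-sensitive (N-pathway) flux is
    ``NS_P - S-linked OXPHOS``; its decline relative to the untreated baseline
    gives the percent N-pathway inhibition.  The paired response variable is
    the S-pathway OXPHOS capacity relative to total ET capacity
    (``S_OXPHOS / NS_E``) of the same run.

    Returns a list of ``(percent_inhibition, relative_S_capacity)`` sorted by
    dose.  Requires a dose-0 baseline.
    """
    doses = [d for d, _ in titration]
    if 0 not in doses and 0.0 not in doses:
        raise ProtocolError("rotenone titration requires a dose-0 baseline")
    by_dose = sorted(titration, key=lambda x: x[0])

    def n_flux(t: SuitStateTable) -> float:
        # rotenone-sensitive share of convergent OXPHOS flux
        return t.flux["NS_P"] - t.flux.get("S_E", 0.0)

    base = by_dose[0][1]
    n0 = n_flux(base)
    if n0 <= 0:
        raise ValueError("baseline N-pathway flux must be positive")
    out = []
    for dose, t in by_dose:
        inhib = 100.0 * (1.0 - n_flux(t) / n0)
        inhib = float(np.clip(inhib, 0.0, 100.0))
        rel_s = t.flux.get("S_E", np.nan) / t.flux["NS_E"]
        out.append((inhib, float(rel_s)))
    return out
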