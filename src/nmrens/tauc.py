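"""Rotational correlation time from the R2/R1 ratio.

For a rigid residue in an isotropically tumbling molecule the ratio R2/R1 of
the ¹⁵N transverse and longitudinal relaxation rates depends only on the
tumbling time and the field, so each residue yields an apparent per-residue
correlation time τc by inverting the rigid-rotor forward model.  Residues
dominated by internal motion or exchange bias the ratio, so before averaging
to a molecular τm the standard two-step filter is applied: drop residues
with a heteronuclear NOE below 0.6 (flexible), then drop residues whose
R2/R1 ratio lies more than one standard deviation from the mean of the
survivors (exchange-broadened or otherwise atypical).  τm is the arithmetic
mean of the remaining per-residue τc values; the spread is reported as both
SD and SEM since either convention appears in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .modelfree import FieldConfig, MotionalParams, RelaxationRecord, predict_rates

__all__ = ["TaucResult", "tauc_from_ratio", "filter_residues", "estimate_tm"]

NOE_CUTOFF = 0.6
DEFAULT_BRACKET = (0.5, 50.0)  # ns


@dataclass
class TaucResult:
    per_residue_tauc: dict[int, float]  # ns, contributing residues only
    excluded: dict[int, str]  # res_seq -> reason
    tau_m: float  # ns
    tau_m_sd: float
    tau_m_sem: float


def _rigid_ratio(tau_c: float, cfg: FieldConfig) -> float:
    p = MotionalParams(model_id=1, S2=1.0, tau_m=tau_c)
    r1, r2, _ = predict_rates(p, cfg)
    return r2 / r1


def tauc_from_ratio(
    R1: float,
    R2: float,
    cfg: FieldConfig,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    res_seq: int | None = None,
) -> float:
    """Solve the rigid isotropic forward model for τc (ns) given R2/R1.

    The rigid-rotor ratio is monotone increasing in τc over the bracket, so
    a Brent root solve is exact to solver tolerance.  Ratios below the rigid
    minimum (or outside the bracket) raise, naming the residue if given.
    """
    who = f" (residue {res_seq})" if res_seq is not None else ""
    ratio = R2 / R1
    if ratio < 1.0:
        raise ValueError(f"R2/R1 = {ratio:.3f} < 1 is infeasible for a rigid rotor{who}")
    lo, hi = bracket
    f_lo = _rigid_ratio(lo, cfg) - ratio
    f_hi = _rigid_ratio(hi, cfg) - ratio
    if f_lo * f_hi > 0:
        raise ValueError(
            f"R2/R1 = {ratio:.3f} has no rigid-rotor solution in [{lo}, {hi}] ns{who}"
        )
    return float(brentq(lambda t: _rigid_ratio(t, cfg) - ratio, lo, hi, xtol=1e-8, rtol=1e-12))


def filter_residues(
    records: list[RelaxationRecord], noe_cutoff: float = NOE_CUTOFF, iterate: bool = False
) -> tuple[list[RelaxationRecord], dict[int, str]]:
    """Two-step exclusion: NOE < cutoff, then |R2/R1 − mean| > 1 SD.

    The ratio statistics are computed over the survivors of the NOE step, and
    the SD trim is a single pass (strict inequality, so a zero-SD set keeps
    everything).  ``iterate=True`` repeats the SD trim to convergence for
    sensitivity analysis; the default single pass is the primary behaviour.
    Order-independent: exclusions depend only on the set of records.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to filter")
    excluded: dict[int, str] = {}
    kept = []
    for rec in records:
        if rec.NOE < noe_cutoff:
            excluded[rec.res_seq] = "low_NOE"
        else:
            kept.append(rec)
    while True:
        if not kept:
            raise ValueError("no residues survive filtering")
        ratios = np.array([r.R2 / r.R1 for r in kept])
        mean, sd = ratios.mean(), ratios.std(ddof=0)
        keep_mask = np.abs(ratios - mean) <= sd
        if keep_mask.all() or not iterate:
            for rec, ok in zip(kept, keep_mask):
                if not ok:
                    excluded[rec.res_seq] = "ratio_outlier"
            kept = [rec for rec, ok in zip(kept, keep_mask) if ok]
            break
        kept = [rec for rec, ok in zip(kept, keep_mask) if ok]
    if not kept:
        raise ValueError("no residues survive filtering")
    return kept, excluded


def estimate_tm(
    records: list[RelaxationRecord],
    cfg: FieldConfig,
    noe_cutoff: float = NOE_CUTOFF,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    iterate: bool = False,
) -> TaucResult:
    """Molecular tumbling time as the mean per-residue τc after filtering."""
    kept, excluded = filter_residues(records, noe_cutoff=noe_cutoff, iterate=iterate)
    taucs: dict[int, float] = {}
    for rec in kept:
        taucs[rec.res_seq] = tauc_from_ratio(rec.R1, rec.R2, cfg, bracket, res_seq=rec.res_seq)
    values = np.array(list(taucs.values()))
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return TaucResult(
        per_residue_tauc=taucs,
        excluded=excluded,
        tau_m=float(values.mean()),
        tau_m_sd=sd,
        tau_m_sem=sd / np.sqrt(len(values)),
    )
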