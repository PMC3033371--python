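"""Linear interaction energy (LIE) binding-affinity estimation.

The binding affinity is approximated as

    ΔG_bind ≈ β * ΔE_elec + α * ΔE_vdw ,   β = 0.5 ,

where ΔE is the ligand–surroundings interaction energy averaged over the
trajectory segments in which the ligand is bound minus the average over the
segments in which it is fully dissociated (COM separation above 15 Å splits
the two).  β = 1/2 has a physical justification (the electrostatic hydration
energy of an ion is half the ion–water interaction energy); α is an empirical
coefficient obtained by linear fitting against reference affinities of
neutral compounds (the model is a poor approximation for charged ligands,
which is surfaced as a warning, not an algorithmic change).  Statistical
errors come from five-block averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LieEstimate",
    "lie_estimate",
    "block_error",
    "fit_alpha",
    "kd_to_delta_g",
]

R_KCAL = 0.0019872041  # kcal / (mol K)
BOUND_CUT = 15.0  # Å
DEFAULT_BETA = 0.5
DEFAULT_ALPHA = 0.56


@dataclass
class LieEstimate:
    delta_e_elec: float  # kcal/mol, bound minus unbound average
    delta_e_vdw: float
    alpha: float
    beta: float
    err_elec: float  # block-averaging error on the delta (quadrature of segments)
    err_vdw: float
    n_bound: int
    n_unbound: int
    charged: bool = False

    @property
    def total(self) -> float:
        return self.beta * self.delta_e_elec + self.alpha * self.delta_e_vdw


def block_error(series: np.ndarray, n_blocks: int = 5) -> float:
    """Block-averaging standard error of the mean.

    The series is split into ``n_blocks`` contiguous blocks of equal length
    (any remainder joins the last block); the error is the standard deviation
    of the block means divided by sqrt(n_blocks).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} cannot form {n_blocks} blocks")
    size = len(x) // n_blocks
    means = [
        x[k * size : (k + 1) * size if k < n_blocks - 1 else len(x)].mean()
        for k in range(n_blocks)
    ]
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))


def lie_estimate(
    frames: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    bound_cut: float = BOUND_CUT,
    n_blocks: int = 5,
    charged: bool = False,
) -> LieEstimate:
    """Term-wise bound/unbound averages and the weighted LIE total.

    ``frames`` needs columns e_elec, e_vdw and com_distance (the bound label
    is com_distance < ``bound_cut``).  Unbound segments of all runs are
    pooled before averaging.
    """
    for col in ("e_elec", "e_vdw", "com_distance"):
        if col not in frames.columns:
            raise ValueError(f"energy table lacks column {col}")
    bound = frames["com_distance"].to_numpy() < bound_cut
    if not bound.any():
        raise ValueError("no bound segment: cannot form the LIE difference")
    if bound.all():
        raise ValueError("no unbound segment: cannot form the LIE difference")
    if charged:
        warnings.warn(
            "LIE with fixed charges is a poor approximation for charged "
            "ligands (missing polarization); interpret the total with care",
            RuntimeWarning,
            stacklevel=2,
        )
    e = frames["e_elec"].to_numpy(dtype=float)
    v = frames["e_vdw"].to_numpy(dtype=float)
    d_elec = e[bound].mean() - e[~bound].mean()
    d_vdw = v[bound].mean() - v[~bound].mean()
    err_e = np.hypot(block_error(e[bound], n_blocks), block_error(e[~bound], n_blocks))
    err_v = np.hypot(block_error(v[bound], n_blocks), block_error(v[~bound], n_blocks))
    return LieEstimate(
        delta_e_elec=float(d_elec),
        delta_e_vdw=float(d_vdw),
        alpha=float(alpha),
        beta=float(beta),
        err_elec=float(err_e),
        err_vdw=float(err_v),
        n_bound=int(bound.sum()),
        n_unbound=int((~bound).sum()),
        charged=charged,
    )


def fit_alpha(
    estimates: list[LieEstimate],
    reference_affinities: list[float],
    neutral: list[bool] | None = None,
    beta: float = DEFAULT_BETA,
) -> tuple[float, pd.DataFrame]:
    """Least-squares van der Waals coefficient against reference affinities.

    Minimizes sum over ligands of (β ΔE_elec + α ΔE_vdw − ΔG_ref)² with β
    fixed; only ligands flagged neutral enter the fit (charged ligands and
    ligands with ΔE_vdw ≈ 0 are excluded from the normal equations but stay
    in the residual report).  Returns (alpha, residual table).
    """
    if len(estimates) != len(reference_affinities):
        raise ValueError("one reference affinity per estimate required")
    if neutral is None:
        neutral = [not e.charged for e in estimates]
    dv = np.array([e.delta_e_vdw for e in estimates])
    de = np.array([e.delta_e_elec for e in estimates])
    ref = np.asarray(reference_affinities, dtype=float)
    usable = np.asarray(neutral, dtype=bool) & (np.abs(dv) > 1e-12)
    if usable.sum() < 2:
        raise ValueError("need at least 2 neutral ligands with ΔE_vdw != 0")
    resid_target = ref[usable] - beta * de[usable]
    alpha = float(dv[usable] @ resid_target / (dv[usable] @ dv[usable]))
    report = pd.DataFrame(
        {
            "delta_e_elec": de,
            "delta_e_vdw": dv,
            "reference": ref,
            "fitted_total": beta * de + alpha * dv,
            "in_fit": usable,
        }
    )
    report["residual"] = report["fitted_total"] - report["reference"]
    return alpha, report


def kd_to_delta_g(kd_molar: float, temperature: float = 310.0) -> float:
    """Binding free energy (kcal/mol) from a dissociation constant (molar
    standard state): ΔG = RT ln K_d."""
    if kd_molar <= 0:
        raise ValueError("K_d must be positive")
    return float(R_KCAL * temperature * np.log(kd_molar))


def write_estimate_tsv(est: LieEstimate, path) -> None:
    pd.DataFrame(
        [
            {
                "delta_e_elec": est.delta_e_elec,
                "delta_e_vdw": est.delta_e_vdw,
                "err_elec": est.err_elec,
                "err_vdw": est.err_vdw,
                "alpha": est.alpha,
                "beta": est.beta,
                "total_kcal_mol": est.total,
                "n_bound": est.n_bound,
                "n_unbound": est.n_unbound,
            }
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
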