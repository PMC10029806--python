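"""Log–log response-coefficient decomposition of multiplicative trait identities.

The mesophyll surface area per leaf area obeys the exact identity

    S_m,LA = S_m,Vcl · (1 − θ_ias) · f_mes · L_leaf

so a between-condition difference in the target can be attributed to its
factors through response coefficients

    RC_x = Δlog(x) / Δlog(T)

which, whenever the identity holds in both conditions, sum to exactly 1 —
each RC is the share of the (log) change in the target carried by one
factor.  The same machinery applies to any multiplicative identity (for
example an LMA decomposition).  The module also provides the area-, mass-
and volume-based normalizations of net assimilation and per-volume
concentrations used to compare leaves of different construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSet",
    "RCResult",
    "multiplicative_rc",
    "group_mean_logs",
    "normalize_assimilation",
    "per_volume_concentration",
]


@dataclass
class FactorSet:
    """Named positive factors of a multiplicative identity and its target.

    If *target* is omitted it is taken as the product of the factors; if
    supplied, it must match the product to 1e-6 relative.
    """

    factors: dict[str, float]
    target: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("at least one factor required")
        for name, value in self.factors.items():
            if not value > 0:
                raise ValueError(f"factor {name!r} must be positive, got {value}")
        product = math.prod(self.factors.values())
        if self.target is None:
            self.target = product
        else:
            if not self.target > 0:
                raise ValueError("target must be positive")
            if abs(product - self.target) / self.target >= 1e-6:
                raise ValueError(
                    f"factor product {product:.6g} does not match target "
                    f"{self.target:.6g} (identity violated)"
                )


@dataclass
class RCResult:
    """Per-factor response coefficients for one condition contrast."""

    rc: dict[str, float]
    relative_contribution_pct: dict[str, float]
    delta_log_target: float
    rc_sum: float = field(init=False)

    def __post_init__(self) -> None:
        self.rc_sum = float(sum(self.rc.values()))


def multiplicative_rc(reference: FactorSet, treatment: FactorSet) -> RCResult:
    """Response coefficients of a treatment-vs-reference contrast.

    RC_x = (log x_treatment − log x_reference) / (log T_treatment − log
    T_reference); the log base cancels in the ratio.  Relative
    contributions are the RCs expressed as signed percentages.
    """
    if set(reference.factors) != set(treatment.factors):
        raise ValueError("factor names must match between conditions")
    dlog_t = math.log(treatment.target) - math.log(reference.target)
    if abs(dlog_t) <= 1e-12:
        raise ValueError("targets are identical; response coefficients undefined")
    rc = {
        name: (math.log(treatment.factors[name]) - math.log(reference.factors[name]))
        / dlog_t
        for name in reference.factors
    }
    return RCResult(
        rc=rc,
        relative_contribution_pct={k: 100.0 * v for k, v in rc.items()},
        delta_log_target=dlog_t,
    )


def group_mean_logs(
    table: pd.DataFrame,
    factor_columns: list[str],
    group_columns: list[str],
) -> dict[tuple, FactorSet]:
    """Geometric-mean factors per condition×group cell.

    All factor values are log-transformed, averaged within each cell, and
    exponentiated back; the target is recomputed from the mean-log factors
    (i.e. as the product of the geometric means), never averaged
    independently — so the multiplicative identity holds exactly in every
    cell.
    """
    for col in factor_columns + group_columns:
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    if (table[factor_columns] <= 0).any().any():
        raise ValueError("all factor values must be positive")
    out: dict[tuple, FactorSet] = {}
    grouped = table.groupby(group_columns, sort=True)
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        if len(sub) == 0:
            raise ValueError(f"empty group cell {key}")
        mean_logs = np.log(sub[factor_columns].to_numpy(dtype=float)).mean(axis=0)
        factors = {c: float(np.exp(m)) for c, m in zip(factor_columns, mean_logs)}
        out[key] = FactorSet(factors=factors, label="/".join(map(str, key)))
    return out


def normalize_assimilation(
    A_area: float,
    LMA: float,
    V_leaf_per_LA_um: float,
    V_cl_per_LA_um: float,
) -> tuple[float, float, float]:
    """Assimilation per mass and per volume from the area-based rate.

    Parameters
    ----------
    A_area
        Net assimilation per leaf area, µmol m⁻² s⁻¹.
    LMA
        Leaf dry mass per area, g m⁻².
    V_leaf_per_LA_um, V_cl_per_LA_um
        Leaf volume and mesophyll cell volume per leaf area, i.e.
        effective depths in µm.

    Returns
    -------
    (A_mass, A_Vleaf, A_Vcl)
        µmol g⁻¹ s⁻¹, mol m⁻³ s⁻¹ and mol m⁻³ s⁻¹ respectively.
    """
    if min(A_area, LMA, V_leaf_per_LA_um, V_cl_per_LA_um) <= 0:
        raise ValueError("all inputs must be positive")
    a_mass = A_area / LMA
    a_mol = A_area * 1e-6  # mol m-2 s-1
    a_vleaf = a_mol / (V_leaf_per_LA_um * 1e-6)
    a_vcl = a_mol / (V_cl_per_LA_um * 1e-6)
    return a_mass, a_vleaf, a_vcl


def per_volume_concentration(
    conc_per_area: float, cellular_volume_per_LA_um: float
) -> float:
    """Convert an areal concentration to a cellular-volume basis.

    The cellular volume per leaf area (leaf volume minus airspace, per
    area) is an effective depth in µm; the result is per m³.
    """
    if cellular_volume_per_LA_um <= 0:
        raise ValueError("cellular volume per area must be positive")
    if conc_per_area <= 0:
        raise ValueError("concentration must be positive")
    return conc_per_area / (cellular_volume_per_LA_um * 1e-6)
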