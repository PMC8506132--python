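"""Michaelis-Menten kinetics: rate conversion, fitting and catalytic efficiency.

Initial velocities are measured spectrophotometrically by following NADH
formation at 340 nm; absorbance slopes are converted to chemical rates with
the Beer-Lambert law (NADH extinction coefficient 6.22 mM^-1 cm^-1).  The
hyperbolic saturation model

    v(s) = Vmax * s / (KM + s)

is fitted to (s, v) observations by unweighted nonlinear least squares, and
catalytic efficiencies kcat/KM are reported as apparent second-order rate
constants in M^-1 s^-1.

Unit conventions: substrate concentrations in mM, velocities in mM min^-1
(1 U ml^-1 == 1 umol min^-1 ml^-1 == 1 mM min^-1 in the cuvette), enzyme
concentration in M.  kcat in s^-1 is Vmax / [E] after converting Vmax to
M s^-1.  Conversion to molar units happens only inside
:func:`catalytic_efficiency`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitConvergenceError, InvalidParameterError

__all__ = [
    "RateConversion",
    "RateResult",
    "KineticDataset",
    "KineticParams",
    "rate_from_absorbance",
    "michaelis_menten",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "normalize_activity",
    "round_sig",
    "read_kinetics_csv",
    "write_fit_report",
]

#: Columns expected in a kinetics CSV (comment lines start with '#').
KINETICS_CSV_COLUMNS = ["condition", "substrate", "s_mM", "v", "replicate"]


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures (0 stays 0)."""
    if sig < 1:
        raise InvalidParameterError("sig must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)


@dataclass(frozen=True)
class RateConversion:
    """Beer-Lambert conversion constants for NADH at 340 nm.

    Parameters
    ----------
    extinction_mM_cm : float
        Molar (per-mM) extinction coefficient, default 6.22 mM^-1 cm^-1.
    path_cm : float
        Optical path length in cm (plate readers apply a 1 cm correction).
    enzyme_conc_M : float, optional
        Enzyme molar concentration, used downstream for kcat.
    enzyme_mg_per_ml : float, optional
        Enzyme mass concentration; enables specific activity in U mg^-1.
    """

    extinction_mM_cm: float = 6.22
    path_cm: float = 1.0
    enzyme_conc_M: Optional[float] = None
    enzyme_mg_per_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.extinction_mM_cm > 0):
            raise InvalidParameterError("extinction coefficient must be > 0")
        if not (self.path_cm > 0):
            raise InvalidParameterError("path length must be > 0")


@dataclass(frozen=True)
class RateResult:
    """Velocity in mM min^-1 plus specific activity when enzyme mass is known."""

    velocity_mM_min: float
    specific_activity_U_mg: Optional[float] = None


def rate_from_absorbance(slope_per_min: float, conv: RateConversion) -> RateResult:
    """Convert an A340 slope (ΔA min^-1) to a velocity in mM min^-1.

    v = slope / (ε · l).  1 mM min^-1 equals 1 U ml^-1, so when
    ``conv.enzyme_mg_per_ml`` is given the specific activity
    v / (mg ml^-1) in U mg^-1 is reported as well.
    """
    if not math.isfinite(slope_per_min):
        raise InvalidParameterError("absorbance slope must be finite")
    v = slope_per_min / (conv.extinction_mM_cm * conv.path_cm)
    spec = None
    if conv.enzyme_mg_per_ml is not None:
        if not (conv.enzyme_mg_per_ml > 0):
            raise InvalidParameterError("enzyme mass concentration must be > 0")
        spec = v / conv.enzyme_mg_per_ml  # U/ml divided by mg/ml
    return RateResult(velocity_mM_min=v, specific_activity_U_mg=spec)


@dataclass
class KineticDataset:
    """Substrate-saturation observations for one condition.

    ``points`` holds (s, v, replicate_id) triples with s in mM and v in the
    velocity unit of the experiment (mM min^-1 unless pre-normalized).
    """

    condition_label: str
    substrate_name: str
    points: list[tuple[float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s, v, _ in self.points:
            if s < 0:
                raise InvalidParameterError("substrate concentrations must be >= 0")

    @property
    def s(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    @property
    def replicate_ids(self) -> np.ndarray:
        return np.array([p[2] for p in self.points], dtype=int)

    @property
    def n_distinct_s(self) -> int:
        return len(np.unique(self.s))

    @property
    def is_balanced(self) -> bool:
        """True when every replicate covers the same substrate grid."""
        grids = {}
        for s, _, rep in self.points:
            grids.setdefault(rep, set()).add(s)
        return len(set(map(frozenset, grids.values()))) <= 1

    @classmethod
    def from_arrays(
        cls,
        s: Sequence[float],
        v: Sequence[float],
        replicate: Optional[Sequence[int]] = None,
        condition_label: str = "",
        substrate_name: str = "",
    ) -> "KineticDataset":
        if replicate is None:
            replicate = [0] * len(s)
        pts = [(float(a), float(b), int(r)) for a, b, r in zip(s, v, replicate)]
        return cls(condition_label, substrate_name, pts)


@dataclass(frozen=True)
class KineticParams:
    """Fitted Michaelis-Menten parameters for one dataset.

    ``Vmax`` carries the velocity unit of the input; ``KM`` is in mM.
    ``kcat`` (s^-1) is present when the enzyme molar concentration was
    supplied.  ``replicate_sd_*`` are SDs of per-replicate fits when the
    dataset contains >= 2 fittable replicates.
    """

    Vmax: float
    KM: float
    se_Vmax: float
    se_KM: float
    n_points: int
    kcat: Optional[float] = None
    replicate_sd_Vmax: Optional[float] = None
    replicate_sd_KM: Optional[float] = None
    condition_label: str = ""
    substrate_name: str = ""

    def __post_init__(self) -> None:
        if not (self.Vmax > 0 and self.KM > 0):
            raise InvalidParameterError("Vmax and KM must be > 0")
        if self.se_Vmax < 0 or self.se_KM < 0:
            raise InvalidParameterError("standard errors must be >= 0")


def michaelis_menten(s, Vmax: float, KM: float):
    """Hyperbolic saturation velocity Vmax*s/(KM+s)."""
    s = np.asarray(s, dtype=float)
    return Vmax * s / (KM + s)


def _fit_core(s: np.ndarray, v: np.ndarray) -> tuple[float, float, float, float]:
    """Single L-M fit with the deterministic initialization contract."""
    vmax0 = 1.2 * float(np.max(v))
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-6)
    try:
        popt, pcov = curve_fit(
            michaelis_menten, s, v, p0=[vmax0, km0], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitConvergenceError(f"Michaelis-Menten fit did not converge: {exc}")
    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(popt)):
        raise FitConvergenceError("fit produced non-finite parameters")
    if km <= 0 or vmax <= 0:
        raise FitConvergenceError(
            f"fit left the physical domain (Vmax={vmax:.4g}, KM={km:.4g}); "
            "the data may lack curvature"
        )
    if km > 100.0 * float(np.max(s)):
        raise FitConvergenceError(
            f"KM={km:.4g} mM far exceeds the sampled range (max s = "
            f"{np.max(s):.4g} mM): saturation not reached, KM unbounded"
        )
    se_vmax = float(se[0]) if np.isfinite(se[0]) else math.inf
    se_km = float(se[1]) if np.isfinite(se[1]) else math.inf
    if not (math.isfinite(se_vmax) and math.isfinite(se_km)):
        raise FitConvergenceError(
            "singular covariance at the optimum: parameters not identifiable"
        )
    return vmax, km, se_vmax, se_km


def fit_michaelis_menten(
    data: KineticDataset, enzyme_conc_M: Optional[float] = None
) -> KineticParams:
    """Fit Vmax and KM by unweighted nonlinear least squares.

    Deterministic Levenberg-Marquardt started at Vmax0 = 1.2*max(v) and
    KM0 = s at the point whose velocity is closest to Vmax0/2 (no random
    restarts).  Degenerate data (all-zero velocities, or no curvature so
    that KM is unbounded) raise :class:`FitConvergenceError` with a
    diagnostic rather than returning a silent estimate.
    """
    s, v = data.s, data.v
    if data.n_distinct_s < 3:
        raise InvalidParameterError(
            f"need >= 3 distinct substrate concentrations, got {data.n_distinct_s}"
        )
    if np.any(v < 0):
        raise InvalidParameterError("velocities must be >= 0")
    if np.all(v == 0):
        raise FitConvergenceError("all velocities are zero: no signal to fit")

    vmax, km, se_vmax, se_km = _fit_core(s, v)

    kcat = None
    if enzyme_conc_M is not None:
        if not (enzyme_conc_M > 0):
            raise InvalidParameterError("enzyme concentration must be > 0")
        # Vmax mM/min -> M/s, then / [E] in M
        kcat = vmax * 1e-3 / 60.0 / enzyme_conc_M

    rep_sd_vmax = rep_sd_km = None
    reps = data.replicate_ids
    unique_reps = np.unique(reps)
    if len(unique_reps) >= 2:
        per_rep = []
        for r in unique_reps:
            mask = reps == r
            if len(np.unique(s[mask])) >= 3 and np.any(v[mask] > 0):
                try:
                    per_rep.append(_fit_core(s[mask], v[mask])[:2])
                except FitConvergenceError:
                    continue
        if len(per_rep) >= 2:
            arr = np.array(per_rep)
            rep_sd_vmax = float(np.std(arr[:, 0], ddof=1))
            rep_sd_km = float(np.std(arr[:, 1], ddof=1))

    return KineticParams(
        Vmax=vmax,
        KM=km,
        se_Vmax=se_vmax,
        se_KM=se_km,
        n_points=len(s),
        kcat=kcat,
        replicate_sd_Vmax=rep_sd_vmax,
        replicate_sd_KM=rep_sd_km,
        condition_label=data.condition_label,
        substrate_name=data.substrate_name,
    )


def catalytic_efficiency(
    kcat_per_s: float, KM_mM: float, sig_figs: Optional[int] = None
) -> float:
    """kcat/KM in M^-1 s^-1 from kcat in s^-1 and KM in mM.

    Full precision is kept unless ``sig_figs`` is given; tables conventionally
    report two significant figures.
    """
    if not (KM_mM > 0):
        raise InvalidParameterError("KM must be > 0")
    eff = kcat_per_s / (KM_mM * 1e-3)
    if sig_figs is not None:
        eff = round_sig(eff, sig_figs)
    return eff


def normalize_activity(
    values: Iterable[tuple[str, float]], reference_condition: str
) -> list[tuple[str, float]]:
    """Express activities as percent of a reference condition's activity."""
    values = list(values)
    ref = [a for c, a in values if c == reference_condition]
    if not ref:
        raise InvalidParameterError(
            f"reference condition {reference_condition!r} not present"
        )
    if not (ref[0] > 0):
        raise InvalidParameterError("reference activity must be > 0")
    return [(c, 100.0 * a / ref[0]) for c, a in values]


def read_kinetics_csv(path_or_buffer) -> list[KineticDataset]:
    """Read a kinetics CSV (``condition,substrate,s_mM,v,replicate``).

    '#' lines are comments; datasets are grouped by (condition, substrate)
    in order of first appearance.
    """
    df = pd.read_csv(path_or_buffer, comment="#")
    missing = [c for c in KINETICS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"kinetics CSV missing columns: {missing}")
    out = []
    for (cond, sub), grp in df.groupby(["condition", "substrate"], sort=False):
        out.append(
            KineticDataset.from_arrays(
                grp["s_mM"], grp["v"], grp["replicate"],
                condition_label=str(cond), substrate_name=str(sub),
            )
        )
    return out


def write_fit_report(fits: Sequence[KineticParams], path) -> pd.DataFrame:
    """Write one TSV row per condition; efficiencies reported at 2 s.f."""
    rows = []
    for p in fits:
        eff = (
            catalytic_efficiency(p.kcat, p.KM, sig_figs=2)
            if p.kcat is not None
            else None
        )
        rows.append(
            {
                "condition": p.condition_label,
                "substrate": p.substrate_name,
                "Vmax": p.Vmax,
                "se_Vmax": p.se_Vmax,
                "KM_mM": p.KM,
                "se_KM": p.se_KM,
                "kcat_s": p.kcat,
                "efficiency_M_s": eff,
                "n_points": p.n_points,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
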