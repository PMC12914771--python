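"""Morrison tight-binding inhibition kinetics and selectivity profiling.

For a tight-binding competitive inhibitor, free-inhibitor depletion by the
enzyme cannot be neglected and the fractional residual velocity follows
Morrison's quadratic:

    Vi/V0 = 1 - [ (E + I + Ki_app) - sqrt((E + I + Ki_app)^2 - 4 E I) ] / (2 E)

with E the total enzyme, I the total inhibitor, and Ki_app the apparent
inhibition constant.  Under competition with substrate S (Michaelis constant
Km), the intrinsic constant is Ki = Ki_app / (1 + S/Km).

Units: all concentrations are handled internally in nM; substrate and Km
enter in uM (the usual assay scale) and are converted.  The default assay
constants are those of the fluorogenic MMP substrate protocol this package
models: S = 7.5 uM, E = 0.325 nM, and Km = 3.607 / 3.771 / 4.75 uM for
MMP-1 / MMP-3 / MMP-9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import pearson

#: Michaelis constants (uM) of the fluorogenic substrate per enzyme.
KM_UM: dict[str, float] = {"MMP-1": 3.607, "MMP-3": 3.771, "MMP-9": 4.75}

#: Final substrate concentration (uM) in the inhibition assay.
S_UM: float = 7.5

#: Enzyme concentration (nM) in the inhibition assay.
E_NM: float = 0.325


@dataclass(frozen=True)
class KineticParameters:
    """One enzyme/inhibitor parameter set (concentrations nM; S, Km uM)."""

    ki_nm: float
    kiapp_nm: float
    s_um: float = S_UM
    km_um: float = KM_UM["MMP-9"]
    e_nm: float = E_NM

    def __post_init__(self) -> None:
        for name in ("ki_nm", "kiapp_nm", "s_um", "km_um", "e_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        expected = ki_to_kiapp(self.ki_nm, self.s_um, self.km_um)
        if abs(expected - self.kiapp_nm) > 1e-9 * max(expected, self.kiapp_nm):
            raise ValueError("Kiapp inconsistent with Ki*(1 + S/Km)")


@dataclass
class InhibitionCurve:
    """One replicate: inhibitor titration vs relative velocity Vi/V0."""

    inhibitor_nm: np.ndarray
    relative_velocity: np.ndarray
    e_nm: float = E_NM
    replicate: int = 0

    def __post_init__(self) -> None:
        self.inhibitor_nm = np.asarray(self.inhibitor_nm, dtype=np.float64)
        self.relative_velocity = np.asarray(self.relative_velocity, dtype=np.float64)
        if self.inhibitor_nm.shape != self.relative_velocity.shape:
            raise ValueError("concentration and velocity arrays must align")
        if np.any(self.inhibitor_nm < 0):
            raise ValueError("inhibitor concentrations must be non-negative")


@dataclass
class FluorescenceTrace:
    """Raw plate-reader trace at one inhibitor concentration."""

    times_s: np.ndarray
    fluorescence: np.ndarray
    inhibitor_nm: float = 0.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.fluorescence = np.asarray(self.fluorescence, dtype=np.float64)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


class NoSignalError(ValueError):
    """No inhibition detected (all relative velocities ~ 1)."""


def morrison_relative_velocity(e_nm: float, i_nm, kiapp_nm: float):
    """Morrison fractional velocity Vi/V0 (vectorised over I).

    Uses the algebraically equivalent form 1 - 2EI / (b + sqrt(b^2 - 4EI))
    with b = E + I + Kiapp, which avoids catastrophic cancellation when the
    discriminant is small (strong inhibition, I >> E).
    """
    if e_nm <= 0:
        raise ValueError("enzyme concentration must be positive")
    if kiapp_nm <= 0:
        raise ValueError("Kiapp must be positive")
    i_nm = np.asarray(i_nm, dtype=np.float64)
    if np.any(i_nm < 0):
        raise ValueError("inhibitor concentration must be non-negative")
    b = e_nm + i_nm + kiapp_nm
    disc = np.maximum(b**2 - 4.0 * e_nm * i_nm, 0.0)
    v = 1.0 - (2.0 * i_nm) / (b + np.sqrt(disc))
    out = np.clip(v, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def kiapp_to_ki(kiapp_nm: float, s_um: float, km_um: float) -> float:
    """Intrinsic Ki from the apparent constant: Ki = Kiapp / (1 + S/Km)."""
    if km_um <= 0:
        raise ValueError("Km must be positive")
    if s_um < 0 or kiapp_nm <= 0:
        raise ValueError("S must be >= 0 and Kiapp > 0")
    return kiapp_nm / (1.0 + s_um / km_um)


def ki_to_kiapp(ki_nm: float, s_um: float, km_um: float) -> float:
    """Apparent constant under substrate competition: Kiapp = Ki (1 + S/Km)."""
    if km_um <= 0:
        raise ValueError("Km must be positive")
    if s_um < 0 or ki_nm <= 0:
        raise ValueError("S must be >= 0 and Ki > 0")
    return ki_nm * (1.0 + s_um / km_um)


def initial_rate(
    trace: FluorescenceTrace,
    window_s: float = 300.0,
    auto: bool = False,
    min_points: int = 10,
) -> float:
    """Initial velocity (fluorescence units/s) from the linear early phase.

    Default: least-squares slope over the first ``window_s`` seconds.  With
    ``auto=True``, scans all contiguous windows of at least ``min_points``
    points starting at t=0-anchored prefixes and keeps the one maximizing
    R^2 (longest on ties), a simple guard against curvature at late times.
    """
    t, f = trace.times_s, trace.fluorescence
    if auto:
        best: tuple[float, int, float] | None = None
        for end in range(min_points, len(t) + 1):
            res = stats.linregress(t[:end], f[:end])
            r2 = res.rvalue**2 if np.isfinite(res.rvalue) else 1.0
            if best is None or (r2, end) > (best[0], best[1]):
                best = (r2, end, res.slope)
        if best is None:
            raise ValueError("trace too short for automatic window selection")
        return float(best[2])
    mask = t <= t[0] + window_s
    if mask.sum() < 5:
        raise ValueError("fewer than 5 points in the initial-rate window")
    if np.allclose(f[mask], f[mask][0]):
        return 0.0
    return float(stats.linregress(t[mask], f[mask]).slope)


def fit_kiapp_single(curve: InhibitionCurve) -> float:
    """Nonlinear least-squares fit of Kiapp for one replicate.

    Kiapp is the sole free parameter of the Morrison model; the initial
    guess is the inhibitor concentration closest to half-maximal inhibition
    (bounded positive).
    """
    i_nm, v = curve.inhibitor_nm, curve.relative_velocity
    if len(np.unique(i_nm)) < 4:
        raise ValueError("need at least 4 distinct inhibitor concentrations")
    if np.all(v > 0.95):
        raise NoSignalError("no inhibition signal in curve")
    half_idx = int(np.argmin(np.abs(v - 0.5)))
    guess = max(float(i_nm[half_idx]), 1e-6)
    popt, _ = optimize.curve_fit(
        lambda i, kiapp: morrison_relative_velocity(curve.e_nm, i, kiapp),
        i_nm,
        v,
        p0=[guess],
        bounds=(1e-12, np.inf),
        maxfev=10000,
    )
    return float(popt[0])


@dataclass
class KiFitResult:
    ki_nm: float
    ki_sd_nm: float
    kiapp_nm: float
    kiapp_sd_nm: float
    replicate_ki_nm: list[float]


def fit_ki(
    curves: Sequence[InhibitionCurve], s_um: float, km_um: float
) -> KiFitResult:
    """Fit Ki from replicate inhibition curves at fixed S and Km.

    Each replicate is fit independently (global least squares across its
    concentration points with a shared Kiapp), converted to Ki via
    Ki = Kiapp/(1 + S/Km), and the result reported as mean +/- sample SD
    across replicates (SD = 0 for a single replicate).
    """
    if not curves:
        raise ValueError("need at least one inhibition curve")
    kiapps = [fit_kiapp_single(c) for c in curves]
    kis = [kiapp_to_ki(k, s_um, km_um) for k in kiapps]
    sd = float(np.std(kis, ddof=1)) if len(kis) > 1 else 0.0
    sd_app = float(np.std(kiapps, ddof=1)) if len(kiapps) > 1 else 0.0
    return KiFitResult(
        ki_nm=float(np.mean(kis)),
        ki_sd_nm=sd,
        kiapp_nm=float(np.mean(kiapps)),
        kiapp_sd_nm=sd_app,
        replicate_ki_nm=kis,
    )


# ---------------------------------------------------------------------------
# Selectivity profiles
# ---------------------------------------------------------------------------

@dataclass
class SelectivityProfile:
    """Per-enzyme Ki and fold change relative to a reference enzyme."""

    ki_nm: dict[str, float]
    reference: str
    fold_change: dict[str, float] = field(init=False)
    fold_change_display: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        if self.reference not in self.ki_nm:
            raise ValueError(f"reference enzyme {self.reference!r} missing from Ki map")
        ref = self.ki_nm[self.reference]
        if ref <= 0:
            raise ValueError("reference Ki must be positive")
        self.fold_change = {enz: ki / ref for enz, ki in self.ki_nm.items()}
        self.fold_change_display = {
            enz: _format_fold(fold) for enz, fold in self.fold_change.items()
        }


def _format_fold(fold: float) -> str:
    # Table style: integers at >= 10, two significant digits below.
    if fold >= 10:
        return str(round(fold))
    return f"{fold:.2g}"


def fold_changes(ki_nm: Mapping[str, float], reference: str) -> SelectivityProfile:
    """Fold change of Ki per enzyme relative to the reference enzyme."""
    return SelectivityProfile(ki_nm=dict(ki_nm), reference=reference)


def ki_er_validation(
    predicted_log2_er: Mapping[str, float],
    measured_ki_nm: Mapping[str, float],
    wt_ki_nm: float,
) -> tuple[list[tuple[float, float]], float]:
    """Correlate predicted log2 ER with WT-normalized log2 Ki.

    Normalizing each variant's Ki by the same-study WT Ki (observed value
    log2(Ki/Ki_WT)) removes inter-study scale differences.  Returns the
    (predicted, observed) pairs and their signed Pearson correlation; the
    sign carries meaning (gates enriched for *low* binders anticorrelate
    with affinity) and is left to the caller to interpret.
    """
    if wt_ki_nm <= 0:
        raise ValueError("WT Ki must be positive")
    shared = sorted(set(predicted_log2_er) & set(measured_ki_nm))
    if len(shared) < 3:
        raise ValueError("need at least 3 variants with both quantities")
    pairs = [
        (float(predicted_log2_er[v]), math.log2(measured_ki_nm[v] / wt_ki_nm))
        for v in shared
    ]
    r = pearson([p for p, _ in pairs], [o for _, o in pairs])
    return pairs, r


def read_inhibition_tsv(path, e_nm: float = E_NM) -> list[InhibitionCurve]:
    """Read inhibition TSV (inhibitor_nM, velocity[, replicate]) into curves."""
    df = pd.read_csv(path, sep="\t")
    if not {"inhibitor_nM", "velocity"} <= set(df.columns):
        raise ValueError("inhibition TSV needs columns inhibitor_nM, velocity")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    curves = []
    for rep, sub in df.groupby("replicate"):
        curves.append(
            InhibitionCurve(
                inhibitor_nm=sub["inhibitor_nM"].to_numpy(),
                relative_velocity=sub["velocity"].to_numpy(),
                e_nm=e_nm,
                replicate=int(rep),
            )
        )
    return curves
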