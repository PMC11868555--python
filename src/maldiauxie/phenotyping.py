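"""Plate-reader growth-curve analysis: diauxie detection and phase yields.

The pipeline mirrors standard plate-reader practice: subtract the medium
background (blank wells), undo the saturating OD–cell-density
nonlinearity with a calibration curve, smooth log OD to get the specific
growth rate mu(t) = d/dt log OD, and read the phenotype off mu(t).  A
diauxic curve shows two growth-rate maxima separated by an interior
minimum; the OD at that minimum, OD_switch, splits the total yield into
the first-phase yield OD1 = OD_switch - OD(0) and the second-phase yield
OD2 = OD(final) - OD_switch, which track the concentrations of the
preferred and the deferred sugar respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import PchipInterpolator, make_smoothing_spline
from scipy.signal import find_peaks
from scipy.stats import ttest_ind

__all__ = [
    "GrowthCurve",
    "PlateData",
    "CalibrationCurve",
    "SmootherConfig",
    "GrowthRateEstimate",
    "DetectionConfig",
    "DiauxiePhenotype",
    "ExponentialPhase",
    "YieldRegression",
    "GrowthRateComparison",
    "read_plate_table",
    "plate_from_frames",
    "preprocess",
    "average_technical_replicates",
    "estimate_growth_rate",
    "detect_diauxie",
    "find_exponential_phase",
    "regress_phase_yields",
    "fluorescence_per_od",
    "compare_growth_rates",
    "phenotype_plate",
]

MIN_POINTS = 20
OD_FLOOR = 1e-4


@dataclass
class GrowthCurve:
    """One well's OD time series (time in hours, strictly increasing)."""

    well: str
    time: np.ndarray
    od: np.ndarray
    fluorescence: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.ndim != 1 or self.od.shape != self.time.shape:
            raise ValueError("time and od must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"well {self.well}: time must be strictly increasing")
        if not np.all(np.isfinite(self.od)):
            raise ValueError(f"well {self.well}: od must be finite")
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)
            if self.fluorescence.shape != self.time.shape:
                raise ValueError(f"well {self.well}: fluorescence length mismatch")


@dataclass
class PlateData:
    """Curves joined to their layout: samples plus blank groups per medium."""

    samples: list[GrowthCurve]
    blanks: dict[tuple, list[GrowthCurve]]
    unmatched_wells: list[str]

    def blanks_for(self, curve: GrowthCurve) -> list[GrowthCurve]:
        key = _medium_key(curve.meta)
        if key in self.blanks:
            return self.blanks[key]
        # fall back to any blank: the medium background barely depends on
        # the sugar concentrations
        pooled = [b for group in self.blanks.values() for b in group]
        return pooled


def _medium_key(meta: dict) -> tuple:
    return (meta.get("sugar_1"), meta.get("conc_1"), meta.get("sugar_2"), meta.get("conc_2"))


_LAYOUT_COLS = ["well", "strain", "sugar_1", "conc_1", "sugar_2", "conc_2", "role"]


def read_plate_table(data_file: str | Path, layout_file: str | Path) -> PlateData:
    """Load a long-format plate CSV (well, time_h, od[, fluor_*]) and its
    layout CSV, returning curves joined to conditions."""
    return plate_from_frames(pd.read_csv(data_file), pd.read_csv(layout_file))


def plate_from_frames(data: pd.DataFrame, layout: pd.DataFrame) -> PlateData:
    """As :func:`read_plate_table`, but on in-memory tables."""
    for col in ("well", "time_h", "od"):
        if col not in data.columns:
            raise ValueError(f"data file missing column {col!r}")
    missing = [c for c in _LAYOUT_COLS if c not in layout.columns]
    if missing:
        raise ValueError(f"layout file missing columns: {missing}")
    fluor_cols = [c for c in data.columns if c.startswith("fluor")]
    data_wells = set(data["well"])
    layout_wells = set(layout["well"])
    absent = sorted(layout_wells - data_wells)
    if absent:
        raise ValueError(f"layout references wells absent from data: {absent}")
    unmatched = sorted(data_wells - layout_wells)

    samples: list[GrowthCurve] = []
    blanks: dict[tuple, list[GrowthCurve]] = {}
    for _, lrow in layout.iterrows():
        well = lrow["well"]
        sub = data[data["well"] == well].sort_values("time_h")
        meta = {c: lrow[c] for c in layout.columns if c != "well"}
        fl = sub[fluor_cols[0]].to_numpy() if fluor_cols else None
        curve = GrowthCurve(
            well=well, time=sub["time_h"].to_numpy(), od=sub["od"].to_numpy(),
            fluorescence=fl, meta=meta,
        )
        if lrow["role"] == "blank":
            blanks.setdefault(_medium_key(meta), []).append(curve)
        else:
            samples.append(curve)
    return PlateData(samples=samples, blanks=blanks, unmatched_wells=unmatched)


class CalibrationCurve:
    """Strictly increasing map from measured OD to a corrected cell-density
    proxy, with its inverse (monotone PCHIP through a lookup table)."""

    def __init__(self, measured: np.ndarray, corrected: np.ndarray):
        measured = np.asarray(measured, dtype=float)
        corrected = np.asarray(corrected, dtype=float)
        if np.any(np.diff(measured) <= 0) or np.any(np.diff(corrected) <= 0):
            raise ValueError("calibration must be strictly increasing")
        self._fwd = PchipInterpolator(measured, corrected, extrapolate=True)
        self._inv = PchipInterpolator(corrected, measured, extrapolate=True)
        self.domain = (float(measured[0]), float(measured[-1]))

    def __call__(self, od):
        return self._fwd(od)

    def inverse(self, corrected):
        return self._inv(corrected)

    @classmethod
    def identity(cls) -> "CalibrationCurve":
        x = np.linspace(0.0, 10.0, 11)
        return cls(x, x)

    @classmethod
    def from_table(cls, path: str | Path) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return cls(df["measured"].to_numpy(), df["corrected"].to_numpy())


def preprocess(
    curve: GrowthCurve,
    blanks: list[GrowthCurve] | None,
    calibration: CalibrationCurve | None = None,
    epsilon: float = OD_FLOOR,
) -> GrowthCurve:
    """Blank-subtract, calibrate and floor one curve.

    od <- max(calibration(od - median blank OD), epsilon).  Fluorescence
    is blank-subtracted too.  A missing blank group degrades to zero
    background with a provenance record (no exception)."""
    meta = dict(curve.meta)
    if blanks:
        bg = float(np.median(np.concatenate([b.od for b in blanks])))
        meta["blank_od"] = bg
        fl_bg = (
            float(np.median(np.concatenate([b.fluorescence for b in blanks if b.fluorescence is not None])))
            if any(b.fluorescence is not None for b in blanks)
            else 0.0
        )
    else:
        import warnings

        warnings.warn(f"well {curve.well}: no blank group; using zero background")
        bg, fl_bg = 0.0, 0.0
        meta["blank_od"] = 0.0
        meta["blank_missing"] = True
    meta["blank_fluor"] = fl_bg
    od = curve.od - bg
    if calibration is not None:
        od = np.asarray(calibration(od), dtype=float)
    od = np.maximum(od, epsilon)
    fl = None if curve.fluorescence is None else curve.fluorescence - fl_bg
    meta["preprocessed"] = True
    return GrowthCurve(well=curve.well, time=curve.time.copy(), od=od, fluorescence=fl, meta=meta)


def average_technical_replicates(curves: list[GrowthCurve]) -> GrowthCurve:
    """Pointwise mean of technical replicates; the across-replicate
    standard deviation is kept in ``meta['od_sd']``."""
    if not curves:
        raise ValueError("no curves to average")
    t0 = curves[0].time
    for c in curves[1:]:
        if c.time.shape != t0.shape or not np.allclose(c.time, t0):
            raise ValueError("technical replicates must share a time grid")
    ods = np.vstack([c.od for c in curves])
    meta = dict(curves[0].meta)
    meta["od_sd"] = ods.std(axis=0, ddof=0)
    meta["n_technical"] = len(curves)
    fl = None
    if all(c.fluorescence is not None for c in curves):
        fl = np.vstack([c.fluorescence for c in curves]).mean(axis=0)
    return GrowthCurve(well=curves[0].well, time=t0.copy(), od=ods.mean(axis=0), fluorescence=fl, meta=meta)


@dataclass(frozen=True)
class SmootherConfig:
    """Settings of the log-OD smoother.

    ``method`` is 'spline' (penalised cubic spline, GCV-chosen penalty
    unless ``lam`` is given) or 'gp' (Gaussian-process regression with a
    squared-exponential kernel, maximum-likelihood hyperparameters).
    ``n_boot`` > 0 replaces the cheap residual-based uncertainty band of
    the spline with a residual-bootstrap band."""

    method: str = "spline"
    lam: float | None = None
    lam_max: float = 50.0  # cap on the GCV penalty (h^4); ~2.7 h bandwidth
    n_boot: int = 0
    boot_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("spline", "gp"):
            raise ValueError("method must be 'spline' or 'gp'")


@dataclass
class GrowthRateEstimate:
    """Smoothed specific growth rate mu(t) = d/dt log OD with a pointwise
    uncertainty half-width."""

    time: np.ndarray
    mu: np.ndarray
    band: np.ndarray
    log_od_smooth: np.ndarray
    settings: SmootherConfig

    @property
    def mu_max(self) -> float:
        return float(np.max(self.mu))


def _local_noise_sd(y: np.ndarray, window: int = 15) -> np.ndarray:
    """Pointwise noise sd of a series from a rolling median absolute
    deviation of its second differences (trend-free, so smooth growth does
    not masquerade as noise; log OD noise grows sharply as the signal
    approaches the blank level, so weights must follow the data)."""
    d2 = np.abs(np.diff(y, n=2)) / np.sqrt(6.0)
    d = np.concatenate([[d2[0]], d2, [d2[-1]]])
    half = window // 2
    sd = np.empty_like(d)
    for i in range(len(d)):
        lo, hi = max(0, i - half), min(len(d), i + half + 1)
        sd[i] = np.median(d[lo:hi])
    return np.maximum(sd * 1.4826, 1e-6)


def _spline_fit(t, y, lam, w=None):
    return make_smoothing_spline(t, y, w=w, lam=lam)


def estimate_growth_rate(curve: GrowthCurve, config: SmootherConfig | None = None) -> GrowthRateEstimate:
    """Estimate mu(t) by smoothing log OD and differentiating analytically."""
    config = config or SmootherConfig()
    if len(curve.time) < MIN_POINTS:
        raise ValueError(f"well {curve.well}: need >= {MIN_POINTS} points, got {len(curve.time)}")
    if np.any(curve.od <= 0):
        raise ValueError(f"well {curve.well}: OD must be positive (preprocess first)")
    t, y = curve.time, np.log(curve.od)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"well {curve.well}: non-finite log OD")
    if config.method == "gp":
        return _estimate_gp(t, y, config)
    w = 1.0 / _local_noise_sd(y) ** 2
    w = w / np.mean(w)
    spl = _spline_fit(t, y, config.lam, w=w)
    if config.lam is None and config.lam_max is not None:
        # GCV can oversmooth curves dominated by a long stationary phase;
        # cap the penalty at the largest value resolving ~hour-scale shifts
        grid = np.geomspace(1e-4, config.lam_max, 12)
        probe = [float(np.max(np.abs(_spline_fit(t, y, lam, w=w)(t) - spl(t)))) for lam in grid]
        if int(np.argmin(probe)) == len(grid) - 1:
            spl = _spline_fit(t, y, config.lam_max, w=w)
    smooth = spl(t)
    mu = spl.derivative()(t)
    resid_sd = float(np.std(y - smooth, ddof=1))
    if config.n_boot > 0:
        rng = np.random.default_rng(config.boot_seed)
        resid = y - smooth
        boots = np.empty((config.n_boot, len(t)))
        for b in range(config.n_boot):
            yb = smooth + rng.choice(resid, size=len(t), replace=True)
            boots[b] = _spline_fit(t, yb, config.lam, w=w).derivative()(t)
        band = boots.std(axis=0, ddof=1)
    else:
        # rough half-width: noise sd propagated through a central difference
        # at the typical sampling interval (upper-bound style estimate)
        dt = float(np.median(np.diff(t)))
        band = np.full_like(mu, resid_sd * np.sqrt(2.0) / (2.0 * dt))
    return GrowthRateEstimate(time=t.copy(), mu=mu, band=np.abs(band), log_od_smooth=smooth, settings=config)


def _estimate_gp(t, y, config: SmootherConfig) -> GrowthRateEstimate:
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

    span = t[-1] - t[0]
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=span / 5, length_scale_bounds=(span / 50, span * 2)
    ) + WhiteKernel(1e-3, (1e-8, 1.0))
    gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True, random_state=0)
    X = t[:, None]
    gp.fit(X, y)
    k = gp.kernel_.k1  # fitted Const * RBF
    amp = float(k.k1.constant_value)
    ell = float(k.k2.length_scale)
    # posterior mean derivative: sum_i alpha_i dk(t, t_i)/dt
    diff = t[:, None] - gp.X_train_[None, :, 0]
    K_cross = amp * np.exp(-0.5 * (diff / ell) ** 2)
    dK = -(diff / ell**2) * K_cross
    y_std = gp._y_train_std
    mu = (dK @ gp.alpha_).ravel() * float(y_std)
    smooth = gp.predict(X)
    # derivative posterior sd: k''(0) - g K^-1 g^T on the training kernel
    from scipy.linalg import cho_solve

    var0 = amp / ell**2
    sol = cho_solve((gp.L_, True), dK.T)
    var = np.maximum(var0 - np.einsum("ij,ji->i", dK, sol), 0.0) * float(y_std) ** 2
    return GrowthRateEstimate(
        time=t.copy(), mu=mu, band=np.sqrt(var), log_od_smooth=smooth, settings=config
    )


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the diauxie caller (all configurable).

    A curve is diauxic when mu(t) has >= 2 maxima of prominence at least
    ``prominence`` (per hour), separated by at least ``min_separation_h``,
    whose interior minimum dips to at most ``depth_ratio`` times the
    smaller peak.  A genuine inter-phase pause drops mu near zero, so the
    depth test separates diauxie from the shallow dip a smoother can ring
    into a plain step-down between growth rates."""

    prominence: float = 0.05
    min_separation_h: float = 2.0
    depth_ratio: float = 0.5
    min_peak_height_frac: float = 0.2  # peaks must reach this fraction of max mu
    min_pause_h: float = 1.5  # the sub-threshold dip must persist this long
    no_growth_od: float = 0.01
    theta_exp: float = 0.9
    theta_lag: float = 0.5


@dataclass
class ExponentialPhase:
    window: tuple[float, float]
    mu_midlog: float
    lag: float


@dataclass
class DiauxiePhenotype:
    """Diauxie call and phase yields for one curve.

    Non-diauxic convention: od1 carries the whole yield, od2 = 0 and the
    switch fields are NaN.  od1 + od2 always equals final - initial OD."""

    well: str
    is_diauxic: bool
    t_switch: float
    od_switch: float
    od1: float
    od2: float
    peak_mus: tuple[float, ...]
    lag: float
    mu_midlog: float
    no_growth: bool = False
    meta: dict = field(default_factory=dict)


def find_exponential_phase(
    estimate: GrowthRateEstimate,
    curve: GrowthCurve,
    theta_exp: float = 0.9,
    theta_lag: float = 0.5,
) -> ExponentialPhase:
    """Exponential window, mid-log rate and lag from the mu(t) profile.

    The window is the maximal contiguous interval around the global
    maximum where mu >= theta_exp * max mu; the lag is the time from the
    start of the record until mu first reaches theta_lag * max mu."""
    mu, t = estimate.mu, estimate.time
    imax = int(np.argmax(mu))
    mmax = mu[imax]
    above = mu >= theta_exp * mmax
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(t) - 1 and above[hi + 1]:
        hi += 1
    window = (float(t[lo]), float(t[hi]))
    mu_midlog = float(np.mean(mu[lo : hi + 1]))
    reach = np.nonzero(mu >= theta_lag * mmax)[0]
    lag = float(t[reach[0]] - t[0]) if reach.size else float(t[-1] - t[0])
    return ExponentialPhase(window=window, mu_midlog=mu_midlog, lag=lag)


def detect_diauxie(
    curve: GrowthCurve,
    estimate: GrowthRateEstimate,
    config: DetectionConfig | None = None,
) -> DiauxiePhenotype:
    """Call diauxie from the growth-rate profile and split the yield.

    Finds mu(t) maxima above the prominence threshold; diauxic iff two
    such maxima bracket an interior minimum deep enough relative to the
    smaller peak.  OD_switch is the (preprocessed) OD at that minimum."""
    config = config or DetectionConfig()
    od0, od_final = float(curve.od[0]), float(curve.od[-1])
    total = od_final - od0
    if total < config.no_growth_od:
        return DiauxiePhenotype(
            well=curve.well, is_diauxic=False, t_switch=np.nan, od_switch=np.nan,
            od1=total, od2=0.0, peak_mus=(), lag=np.nan, mu_midlog=np.nan,
            no_growth=True, meta=dict(curve.meta),
        )
    mu, t = estimate.mu, estimate.time
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(config.min_separation_h / dt)))
    # pad with the global minimum so maxima at the record edges carry their
    # full prominence (growth may already be exponential at the first read)
    mu_padded = np.concatenate([[mu.min()], mu, [mu.min()]])
    peaks, props = find_peaks(mu_padded, prominence=config.prominence, distance=distance)
    peaks = peaks - 1
    # a real growth phase runs at a rate comparable to the fastest phase;
    # drop peaks that are mere noise wiggles on a non-growing baseline
    tall = mu[peaks] >= config.min_peak_height_frac * float(np.max(mu))
    peaks = peaks[tall]
    props = {k: v[tall] for k, v in props.items()}
    phase = find_exponential_phase(estimate, curve, config.theta_exp, config.theta_lag)

    is_diauxic = False
    t_switch = od_switch = np.nan
    od1, od2 = total, 0.0
    peak_mus: tuple[float, ...] = tuple(float(mu[p]) for p in peaks)
    if len(peaks) >= 2:
        # the two most prominent maxima, in time order
        top2 = peaks[np.argsort(props["prominences"])[-2:]]
        p1, p2 = int(np.min(top2)), int(np.max(top2))
        imin = p1 + int(np.argmin(mu[p1 : p2 + 1]))
        theta = config.depth_ratio * min(mu[p1], mu[p2])
        lo_i, hi_i = imin, imin
        while lo_i > p1 and mu[lo_i - 1] <= theta:
            lo_i -= 1
        while hi_i < p2 and mu[hi_i + 1] <= theta:
            hi_i += 1
        pause_h = float(t[hi_i] - t[lo_i])
        # a genuine inter-phase pause is deep AND sustained; a smoother
        # ringing through a step between growth rates is neither for long
        if mu[imin] <= theta and pause_h >= config.min_pause_h:
            is_diauxic = True
            t_switch = float(t[imin])
            od_switch = float(np.interp(t_switch, curve.time, curve.od))
            od1 = od_switch - od0
            od2 = od_final - od_switch
            peak_mus = (float(mu[p1]), float(mu[p2]))
    return DiauxiePhenotype(
        well=curve.well, is_diauxic=is_diauxic, t_switch=t_switch, od_switch=od_switch,
        od1=od1, od2=od2, peak_mus=peak_mus, lag=phase.lag, mu_midlog=phase.mu_midlog,
        meta=dict(curve.meta),
    )


@dataclass
class YieldRegression:
    """OLS of phase yield on sugar concentration."""

    phase: int
    sugar: str
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    points: pd.DataFrame

    def covers(self, true_slope: float) -> bool:
        return self.slope_ci[0] <= true_slope <= self.slope_ci[1]


def regress_phase_yields(
    phenotypes: list[DiauxiePhenotype],
    phase: int,
    sugar: str,
    alpha: float = 0.05,
    diauxic_only: bool = True,
) -> YieldRegression:
    """Regress the phase-1 or phase-2 yield on the named sugar's
    concentration (taken from each phenotype's layout metadata).

    Phase yields are defined through OD_switch, which only exists on
    diauxic curves, so non-diauxic wells are excluded by default."""
    if phase not in (1, 2):
        raise ValueError("phase must be 1 or 2")
    if diauxic_only:
        phenotypes = [ph for ph in phenotypes if ph.is_diauxic]
    rows = []
    for ph in phenotypes:
        meta = ph.meta
        conc = None
        for k in (1, 2):
            if meta.get(f"sugar_{k}") == sugar:
                conc = float(meta[f"conc_{k}"])
        if conc is None:
            raise ValueError(f"well {ph.well}: sugar {sugar!r} not in layout metadata")
        rows.append({"well": ph.well, "concentration": conc, "yield": ph.od1 if phase == 1 else ph.od2})
    points = pd.DataFrame(rows)
    if points["concentration"].nunique() < 3:
        raise ValueError("need >= 3 distinct concentrations for a yield regression")
    X = sm.add_constant(points["concentration"].to_numpy())
    fit = sm.OLS(points["yield"].to_numpy(), X).fit()
    ci = fit.conf_int(alpha)
    return YieldRegression(
        phase=phase, sugar=sugar,
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        points=points,
    )


def fluorescence_per_od(curve: GrowthCurve) -> pd.DataFrame:
    """Fluorescence per OD on a preprocessed curve (blank already
    subtracted), reported against both time and OD."""
    if curve.fluorescence is None:
        raise ValueError(f"well {curve.well}: no fluorescence channel")
    per_od = curve.fluorescence / curve.od
    return pd.DataFrame({"time_h": curve.time, "od": curve.od, "fluor_per_od": per_od})


@dataclass(frozen=True)
class GrowthRateComparison:
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def compare_growth_rates(group_a, group_b) -> GrowthRateComparison:
    """Welch two-sample t-test between two groups of specific growth rates."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    else:
        res = ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return GrowthRateComparison(
        statistic=stat, p_value=p,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
    )


def phenotype_plate(
    plate: PlateData,
    calibration: CalibrationCurve | None = None,
    smoother: SmootherConfig | None = None,
    detection: DetectionConfig | None = None,
) -> tuple[pd.DataFrame, list[DiauxiePhenotype]]:
    """Preprocess, smooth and phenotype every sample well of a plate."""
    phenotypes = []
    for curve in plate.samples:
        pre = preprocess(curve, plate.blanks_for(curve), calibration)
        est = estimate_growth_rate(pre, smoother)
        phenotypes.append(detect_diauxie(pre, est, detection))
    rows = []
    for ph in phenotypes:
        rows.append(
            {
                "well": ph.well,
                "strain": ph.meta.get("strain"),
                "sugar_1": ph.meta.get("sugar_1"),
                "conc_1": ph.meta.get("conc_1"),
                "sugar_2": ph.meta.get("sugar_2"),
                "conc_2": ph.meta.get("conc_2"),
                "is_diauxic": ph.is_diauxic,
                "no_growth": ph.no_growth,
                "t_switch": ph.t_switch,
                "od_switch": ph.od_switch,
                "od1": ph.od1,
                "od2": ph.od2,
                "lag": ph.lag,
                "mu_midlog": ph.mu_midlog,
            }
        )
    return pd.DataFrame(rows), phenotypes
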