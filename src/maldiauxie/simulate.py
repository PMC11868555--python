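"""Synthetic two-sugar batch cultures rendered as plate-reader tables.

Monod kinetics with per-sugar yields is the minimal structure matching the
observed linear yield–concentration relation of diauxic growth: biomass
grows at ``mu = mu_max S/(K+S)`` on the active sugar and each percent
(w/v) of sugar converts to ``Y`` OD units of biomass.  Three consumption
modes are supported:

* ``sequential`` — sugar 1 (the preferred sugar, e.g. galactose) is
  consumed to exhaustion, growth pauses for a fixed lag ``L``, then sugar
  2 (palatinose) is consumed: classic diauxie.
* ``simultaneous`` — both uptake terms are active from the start: no
  diauxie.
* ``regulon`` — as sequential, but the lag emerges from the MAL regulon
  model: at sugar-1 exhaustion the galactose-elevated ``K_T`` steps back
  down and phase-2 uptake starts once the transporter level crosses an
  induction threshold.

Rendering converts true biomass ``B`` to measured OD through a saturating
nonlinearity ``g(B) = B / (1 + a B)`` (plate readers undercount dense
cultures), adds the medium background, and applies multiplicative
(lognormal) then additive Gaussian noise.  A truth table and the exact
inverse of ``g`` (the calibration fixture) are emitted alongside, so
every downstream estimate can be checked against ground truth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .regulon import RegulonParams, RegulonState, simulate_regulon

__all__ = [
    "SugarSpec",
    "CultureConfig",
    "NoiseModel",
    "CultureTruth",
    "PlateLayout",
    "RenderedPlate",
    "simulate_batch_culture",
    "regulon_induction_lag",
    "make_mixture_design",
    "render_plate",
    "simulate_plate",
    "calibration_table",
]

_EXHAUST = 1e-7  # % w/v below which a sugar counts as exhausted


@dataclass(frozen=True)
class SugarSpec:
    """One carbon source: name, initial concentration (% w/v), Monod
    parameters (mu_max per hour, K in % w/v) and biomass yield Y in OD
    units per % w/v."""

    name: str
    conc0: float
    mu_max: float
    K: float = 0.01
    Y: float = 1.0

    def __post_init__(self) -> None:
        if self.conc0 < 0 or self.mu_max < 0 or self.K <= 0 or self.Y <= 0:
            raise ValueError("sugar parameters must be non-negative (K, Y positive)")


@dataclass(frozen=True)
class CultureConfig:
    """Ground-truth settings of one simulated well."""

    sugar1: SugarSpec = SugarSpec("galactose", 0.5, 0.25)
    sugar2: SugarSpec = SugarSpec("palatinose", 0.5, 0.12)
    B0: float = 0.02
    mode: str = "sequential"  # sequential | simultaneous | regulon
    lag_h: float = 3.0  # dead time after sugar-1 exhaustion (sequential)
    initial_lag_h: float = 2.0  # inoculation lag before any growth
    duration_h: float = 48.0
    reporter: bool = False  # phase-2 expression proxy (e.g. Ima5-GFP)
    reporter_rate: float = 1.0  # per hour
    regulon_params: RegulonParams | None = None  # regulon mode, no-galactose params
    regulon_lambda_gal: float = 3.0
    regulon_tau_h: float = 4.0  # hours per regulon time unit (isomaltase turnover)

    def __post_init__(self) -> None:
        if self.mode not in ("sequential", "simultaneous", "regulon"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.B0 <= 0 or self.lag_h < 0 or self.initial_lag_h < 0 or self.duration_h <= 0:
            raise ValueError("B0, duration must be positive; lags non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model of the plate reader."""

    multiplicative_sd: float = 0.02
    additive_sd: float = 0.005
    background_od: float = 0.04
    saturation_a: float = 0.25  # g(B) = B / (1 + a B)
    cadence_h: float = 1.0 / 6.0  # one reading every 10 minutes
    fluor_gain: float = 50.0  # AU per (reporter fraction x OD)
    fluor_background: float = 5.0
    fluor_additive_sd: float = 0.5

    def __post_init__(self) -> None:
        if min(self.multiplicative_sd, self.additive_sd, self.fluor_additive_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.saturation_a < 0 or self.cadence_h <= 0:
            raise ValueError("saturation_a must be >= 0 and cadence positive")

    def saturate(self, B):
        return np.asarray(B) / (1.0 + self.saturation_a * np.asarray(B))

    def desaturate(self, od):
        return np.asarray(od) / (1.0 - self.saturation_a * np.asarray(od))


@dataclass(frozen=True)
class CultureTruth:
    """Noise-free trajectories of one well plus the phase bookkeeping."""

    t: np.ndarray
    B: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    reporter: np.ndarray
    config: CultureConfig
    t_exhaust1: float | None  # sugar-1 exhaustion time
    t_phase2: float | None  # start of phase-2 growth (after the lag)

    def sample(self, times: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "B": np.interp(times, self.t, self.B),
            "S1": np.interp(times, self.t, self.S1),
            "S2": np.interp(times, self.t, self.S2),
            "reporter": np.interp(times, self.t, self.reporter),
        }

    @property
    def od1_true(self) -> float:
        """True first-phase yield Y1*S1_0 (total yield if non-diauxic)."""
        c = self.config
        if self.t_exhaust1 is None:
            return float(self.B[-1] - c.B0)
        return c.sugar1.Y * c.sugar1.conc0


def _monod(mu_max, K, S):
    return mu_max * S / (K + S) if S > 0 else 0.0


def regulon_induction_lag(
    params_no_gal: RegulonParams,
    lambda_gal: float = 3.0,
    tau_h: float = 4.0,
    threshold_factor: float = 2.0,
    horizon: float = 200.0,
) -> float:
    """Lag (hours) for the regulon to induce its transporter after the
    preferred sugar runs out.

    During phase 1 galactose holds ``K_T`` elevated and the regulon sits
    at the low steady state; at exhaustion ``K_T`` steps down and the lag
    is the (dimensionless) time until ``T`` exceeds
    ``threshold_factor * b_T / d_T``, scaled by ``tau_h``.
    """
    gal = params_no_gal.replace(K_T=params_no_gal.K_T * lambda_gal)
    pre = simulate_regulon(
        gal,
        RegulonState(0.0, 0.0, params_no_gal.b_T / params_no_gal.d_T),
        horizon=100.0,
        n_points=2,
    ).end
    traj = simulate_regulon(params_no_gal, pre, horizon=horizon, n_points=4000)
    threshold = threshold_factor * params_no_gal.b_T / params_no_gal.d_T
    above = np.nonzero(traj.T > threshold)[0]
    if above.size == 0:
        return float(horizon * tau_h)
    return float(traj.t[above[0]] * tau_h)


def _integrate_phase(rhs, t0, t1, y0, events=None):
    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", events=events, rtol=1e-9, atol=1e-11, dense_output=True)
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"batch-culture integration failed: {sol.message}")
    return sol


def simulate_batch_culture(config: CultureConfig, dt: float = 0.02) -> CultureTruth:
    """Integrate one well's true biomass, sugars and reporter."""
    c = config
    s1, s2 = c.sugar1, c.sugar2
    t_end = c.duration_h
    segs_t: list[np.ndarray] = []
    segs_y: list[np.ndarray] = []  # rows: B, S1, S2

    def emit(tgrid, B, S1, S2):
        segs_t.append(tgrid)
        segs_y.append(np.vstack([B, S1, S2]))

    t = 0.0
    B, S1, S2 = c.B0, s1.conc0, s2.conc0
    if c.initial_lag_h > 0:
        tg = np.arange(0.0, min(c.initial_lag_h, t_end) + dt / 2, dt)
        emit(tg, np.full_like(tg, B), np.full_like(tg, S1), np.full_like(tg, S2))
        t = min(c.initial_lag_h, t_end)

    t_exhaust1: float | None = None
    t_phase2: float | None = None

    if c.mode == "simultaneous":
        def rhs(tt, y):
            Bv, S1v, S2v = np.maximum(y, 0.0)
            mu1 = _monod(s1.mu_max, s1.K, S1v)
            mu2 = _monod(s2.mu_max, s2.K, S2v)
            return [(mu1 + mu2) * Bv, -mu1 / s1.Y * Bv, -mu2 / s2.Y * Bv]

        if t < t_end:
            sol = _integrate_phase(rhs, t, t_end, [B, S1, S2])
            tg = np.arange(t, t_end + dt / 2, dt)
            y = np.maximum(sol.sol(np.clip(tg, t, sol.t[-1])), 0.0)
            emit(tg, y[0], y[1], y[2])
        t_phase2 = t if s2.conc0 > 0 else None
    else:
        # phase 1: preferred sugar only
        if s1.conc0 > 0 and s1.mu_max > 0 and t < t_end:
            def rhs1(tt, y):
                Bv, S1v = max(y[0], 0.0), max(y[1], 0.0)
                mu1 = _monod(s1.mu_max, s1.K, S1v)
                return [mu1 * Bv, -mu1 / s1.Y * Bv]

            def exhausted(tt, y):
                return y[1] - _EXHAUST

            exhausted.terminal = True
            exhausted.direction = -1.0
            sol = _integrate_phase(rhs1, t, t_end, [B, S1], events=exhausted)
            t1 = float(sol.t[-1])
            tg = np.arange(t, t1 + dt / 2, dt)
            y = np.maximum(sol.sol(np.clip(tg, t, t1)), 0.0)
            emit(tg, y[0], y[1], np.full_like(tg, S2))
            B_end, S1_end = np.maximum(sol.y[:, -1], 0.0)
            B = float(B_end)
            t = t1
            if sol.status == 1:
                t_exhaust1 = t1
                S1 = 0.0
            else:
                S1 = float(S1_end)
        # lag after exhaustion
        if t_exhaust1 is not None and t < t_end and s2.conc0 > 0:
            if c.mode == "regulon":
                if c.regulon_params is None:
                    raise ValueError("regulon mode requires regulon_params")
                lag = regulon_induction_lag(
                    c.regulon_params, c.regulon_lambda_gal, c.regulon_tau_h
                )
            else:
                lag = c.lag_h
            if lag > 0:
                t2 = min(t + lag, t_end)
                tg = np.arange(t, t2 + dt / 2, dt)
                emit(tg, np.full_like(tg, B), np.zeros_like(tg), np.full_like(tg, S2))
                t = t2
            if t < t_end:
                t_phase2 = t
        # phase 2: second sugar
        start_phase2 = t_phase2 is not None or (s1.conc0 == 0 and s2.conc0 > 0)
        if s1.conc0 == 0 and s2.conc0 > 0 and t < t_end:
            t_phase2 = t
            start_phase2 = True
        if start_phase2 and t < t_end and s2.mu_max > 0:
            def rhs2(tt, y):
                Bv, S2v = max(y[0], 0.0), max(y[1], 0.0)
                mu2 = _monod(s2.mu_max, s2.K, S2v)
                return [mu2 * Bv, -mu2 / s2.Y * Bv]

            sol = _integrate_phase(rhs2, t, t_end, [B, S2])
            tg = np.arange(t, t_end + dt / 2, dt)
            y = np.maximum(sol.sol(np.clip(tg, t, sol.t[-1])), 0.0)
            emit(tg, y[0], np.zeros_like(tg), y[1])
            t = t_end

    if t < t_end or not segs_t:
        tg = np.arange(t, t_end + dt / 2, dt)
        emit(tg, np.full_like(tg, B), np.full_like(tg, S1), np.full_like(tg, S2))

    tt = np.concatenate(segs_t)
    yy = np.concatenate(segs_y, axis=1)
    order = np.argsort(tt, kind="stable")
    tt, yy = tt[order], yy[:, order]
    keep = np.concatenate([[True], np.diff(tt) > 1e-12])
    tt, yy = tt[keep], yy[:, keep]

    rep = np.zeros_like(tt)
    if c.reporter and t_phase2 is not None:
        dtp = np.maximum(tt - t_phase2, 0.0)
        rep = 1.0 - np.exp(-c.reporter_rate * dtp)
    return CultureTruth(
        t=tt, B=yy[0], S1=yy[1], S2=yy[2], reporter=rep,
        config=c, t_exhaust1=t_exhaust1, t_phase2=t_phase2,
    )


@dataclass(frozen=True)
class PlateLayout:
    """Well-to-condition map with columns well, strain, sugar_1, conc_1,
    sugar_2, conc_2, replicate, role (sample|blank)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"well", "strain", "sugar_1", "conc_1", "sugar_2", "conc_2", "replicate", "role"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"layout missing columns: {sorted(missing)}")
        if self.table["well"].duplicated().any():
            raise ValueError("layout wells must be unique")

    @property
    def samples(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "sample"]

    @property
    def blanks(self) -> pd.DataFrame:
        return self.table[self.table["role"] == "blank"]


_WELLS_96 = [f"{r}{c}" for r in string.ascii_uppercase[:8] for c in range(1, 13)]


def make_mixture_design(
    conc1: list[float],
    conc2: list[float],
    replicates: int,
    blanks: int = 1,
    strain: str = "WT",
    sugar1: str = "galactose",
    sugar2: str = "palatinose",
) -> PlateLayout:
    """Full-factorial concentration-gradient design on one 96-well plate."""
    if not conc1 or not conc2 or replicates < 1:
        raise ValueError("concentration lists must be non-empty, replicates >= 1")
    n = len(conc1) * len(conc2) * replicates + blanks
    if n > 96:
        raise ValueError(f"design needs {n} wells; a plate has 96")
    rows = []
    k = 0
    for c1 in conc1:
        for c2 in conc2:
            for rep in range(1, replicates + 1):
                rows.append((_WELLS_96[k], strain, sugar1, c1, sugar2, c2, rep, "sample"))
                k += 1
    media = [(c1, c2) for c1 in conc1 for c2 in conc2]
    for b in range(blanks):
        c1, c2 = media[b % len(media)]
        rows.append((_WELLS_96[k], "blank", sugar1, c1, sugar2, c2, b + 1, "blank"))
        k += 1
    table = pd.DataFrame(
        rows, columns=["well", "strain", "sugar_1", "conc_1", "sugar_2", "conc_2", "replicate", "role"]
    )
    return PlateLayout(table)


@dataclass(frozen=True)
class RenderedPlate:
    """Noisy plate-reader tables plus the noiseless truth."""

    plate: pd.DataFrame
    layout: pd.DataFrame
    truth: pd.DataFrame
    truth_summary: pd.DataFrame
    calibration: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("plate", self.plate),
            ("layout", self.layout),
            ("truth", self.truth),
            ("truth_summary", self.truth_summary),
            ("calibration", self.calibration),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.6f")
            paths[name] = p
        return paths


def calibration_table(noise: NoiseModel, max_od: float = 3.0, n: int = 200) -> pd.DataFrame:
    """Exact inverse of the OD saturation as a two-column lookup table."""
    max_measured = float(noise.saturate(max_od))
    measured = np.linspace(0.0, max_measured, n)
    return pd.DataFrame({"measured": measured, "corrected": noise.desaturate(measured)})


def render_plate(
    truths: dict[str, CultureTruth],
    layout: PlateLayout,
    noise: NoiseModel,
    seed: int,
) -> RenderedPlate:
    """Sample trajectories on the reader cadence and apply the noise model.

    Measured OD is ``g(B) * exp(sd_m z) + background + N(0, sd_a)``;
    blank wells carry background plus noise only.  One master seed expands
    into an independent substream per well (sorted well order), so equal
    seeds give byte-identical output tables.
    """
    wells = sorted(layout.table["well"])
    streams = dict(zip(wells, np.random.SeedSequence(seed).spawn(len(wells))))
    duration = max(tr.t[-1] for tr in truths.values()) if truths else 48.0
    times = np.arange(0.0, duration + 1e-9, noise.cadence_h)
    any_reporter = any(tr.config.reporter for tr in truths.values())

    plate_rows, truth_rows, summary_rows = [], [], []
    for _, row in layout.table.sort_values("well").iterrows():
        well = row["well"]
        rng = np.random.default_rng(streams[well])
        if row["role"] == "blank":
            od = noise.background_od + rng.normal(0.0, noise.additive_sd, len(times))
            fluor = noise.fluor_background + rng.normal(0.0, noise.fluor_additive_sd, len(times))
            B = np.zeros_like(times)
            rep = np.zeros_like(times)
        else:
            if well not in truths:
                raise ValueError(f"no trajectory supplied for sample well {well}")
            tr = truths[well]
            s = tr.sample(times)
            B, rep = s["B"], s["reporter"]
            mult = np.exp(rng.normal(0.0, noise.multiplicative_sd, len(times)))
            od = noise.saturate(B) * mult + noise.background_od
            od = od + rng.normal(0.0, noise.additive_sd, len(times))
            fluor = (
                noise.fluor_gain * rep * B
                + noise.fluor_background
                + rng.normal(0.0, noise.fluor_additive_sd, len(times))
            )
            summary_rows.append(
                {
                    "well": well,
                    "t_exhaust1": np.nan if tr.t_exhaust1 is None else tr.t_exhaust1,
                    "t_phase2": np.nan if tr.t_phase2 is None else tr.t_phase2,
                    "od1_true": tr.od1_true,
                    "od_total_true": float(tr.B[-1] - tr.config.B0),
                    "B0": tr.config.B0,
                    "mode": tr.config.mode,
                }
            )
        for k, t in enumerate(times):
            prow = {"well": well, "time_h": t, "od": od[k]}
            if any_reporter:
                prow["fluor_gfp"] = fluor[k]
            plate_rows.append(prow)
            truth_rows.append(
                {
                    "well": well,
                    "time_h": t,
                    "B": B[k],
                    "S1": np.interp(t, truths[well].t, truths[well].S1) if row["role"] == "sample" else 0.0,
                    "S2": np.interp(t, truths[well].t, truths[well].S2) if row["role"] == "sample" else 0.0,
                    "reporter": rep[k],
                }
            )
    return RenderedPlate(
        plate=pd.DataFrame(plate_rows),
        layout=layout.table.copy(),
        truth=pd.DataFrame(truth_rows),
        truth_summary=pd.DataFrame(summary_rows),
        calibration=calibration_table(noise),
    )


def simulate_plate(
    layout: PlateLayout,
    template: CultureConfig,
    noise: NoiseModel,
    seed: int,
    mode_by_strain: dict[str, str] | None = None,
    lag_by_strain: dict[str, float] | None = None,
) -> RenderedPlate:
    """Simulate every sample well of ``layout`` and render the plate.

    Per-well configs are the ``template`` with concentrations taken from
    the layout; ``mode_by_strain`` / ``lag_by_strain`` override consumption
    mode and lag per strain label (e.g. a no-lag, co-consuming ima1Δ)."""
    truths: dict[str, CultureTruth] = {}
    for _, row in layout.samples.iterrows():
        cfg = replace(
            template,
            sugar1=replace(template.sugar1, name=row["sugar_1"], conc0=float(row["conc_1"])),
            sugar2=replace(template.sugar2, name=row["sugar_2"], conc0=float(row["conc_2"])),
        )
        strain = row["strain"]
        if mode_by_strain and strain in mode_by_strain:
            cfg = replace(cfg, mode=mode_by_strain[strain])
        if lag_by_strain and strain in lag_by_strain:
            cfg = replace(cfg, lag_h=lag_by_strain[strain])
        truths[row["well"]] = simulate_batch_culture(cfg)
    return render_plate(truths, layout, noise, seed)
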