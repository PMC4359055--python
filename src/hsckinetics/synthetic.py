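"""Synthetic single-cell division tracks, BrdU time courses and limiting-dilution tables.

Emulates the three kinds of measurements the analysis stages consume:

* interval-censored single-cell division tracking (single LT- and ST-HSCs
  sorted into wells, inspected twice a day over ~140 hr),
* BrdU label-incorporation time courses sampled over 12 days, and
* single-hit Poisson engraftment counts from limiting-dilution transplants.

The generative model for a well is: a latent quiescence-exit duration (G0
exit) plus a cell-cycle transit duration give the true time to first
division; an independent second transit draw gives the interval to the
second division.  Durations are Gaussian, truncated at a small positive
floor.  Events are only seen at the next scheduled inspection (snap-up
interval censoring) and events beyond the observation horizon are censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LT",
    "ST",
    "SubtypeTiming",
    "TimingConfig",
    "SingleCellTrack",
    "BrdUConfig",
    "LDADesign",
    "generate_division_tracks",
    "tracks_to_frame",
    "frame_to_tracks",
    "generate_brdu_series",
    "generate_lda_counts",
]

LT = "LT"
ST = "ST"

#: Durations are truncated-Gaussian; this is the truncation floor in hours.
DURATION_FLOOR = 0.1


def _truncated_normal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    """Gaussian draws truncated (by resampling) at DURATION_FLOOR."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = out < DURATION_FLOOR
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < DURATION_FLOOR
    return out


@dataclass(frozen=True)
class SubtypeTiming:
    """Latent kinetic parameters of one HSC subtype (hours)."""

    mean_g0_exit: float
    sd_g0_exit: float
    mean_cycle_transit: float
    sd_cycle_transit: float

    def validate(self) -> None:
        if self.mean_g0_exit <= 0 or self.mean_cycle_transit <= 0:
            raise ValueError("mean durations must be positive")
        if self.sd_g0_exit < 0 or self.sd_cycle_transit < 0:
            raise ValueError("duration SDs must be nonnegative")


# Shipped defaults: the LT-ST gap in G0 exit is 5.8 hr and the gap in total
# time to first division is 9 hr (hence 3.2 hr in cycle transit).  Absolute
# anchors (ST G0 exit 14.2 hr, ST transit 26.8 hr) and the per-duration SDs
# are this package's choices; only the between-subtype gaps are measured
# quantities.
DEFAULT_LT_TIMING = SubtypeTiming(
    mean_g0_exit=20.0, sd_g0_exit=5.0, mean_cycle_transit=30.0, sd_cycle_transit=6.0
)
DEFAULT_ST_TIMING = SubtypeTiming(
    mean_g0_exit=14.2, sd_g0_exit=5.0, mean_cycle_transit=26.8, sd_cycle_transit=6.0
)


@dataclass(frozen=True)
class TimingConfig:
    """Design of a single-cell division-tracking experiment.

    Defaults reproduce the reference design: 288 wells per subtype (576
    single cells total), inspected every 12 hr (twice a day) over 140 hr.
    """

    n_wells_per_subtype: int = 288
    horizon: float = 140.0
    observation_interval: float = 12.0
    timing: dict = field(
        default_factory=lambda: {LT: DEFAULT_LT_TIMING, ST: DEFAULT_ST_TIMING}
    )
    death_probability: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_wells_per_subtype <= 0:
            raise ValueError("n_wells_per_subtype must be positive")
        if self.observation_interval <= 0:
            raise ValueError("observation_interval must be positive")
        if self.horizon < self.observation_interval:
            raise ValueError("horizon must cover at least one observation interval")
        if not 0.0 <= self.death_probability <= 1.0:
            raise ValueError("death_probability must be in [0, 1]")
        for t in self.timing.values():
            t.validate()

    @property
    def observation_times(self) -> np.ndarray:
        """Scheduled inspection times: every interval up to the horizon."""
        n = int(np.floor(self.horizon / self.observation_interval))
        return self.observation_interval * np.arange(1, n + 1)


@dataclass(frozen=True)
class SingleCellTrack:
    """One well's interval-censored observations for a single plated cell.

    Division times are the observation times at which the division was first
    seen; ``None`` means the event was not observed before the horizon (or
    the cell died first).
    """

    well_id: str
    subtype: str
    first_division_time: float | None
    second_division_time: float | None
    died: bool
    observation_interval: float
    horizon: float


def _snap_up(true_times: np.ndarray, interval: float, horizon: float) -> np.ndarray:
    """Interval-censor event times to the first inspection >= the true time.

    Events beyond the horizon come back as NaN (right-censored).
    """
    snapped = interval * np.ceil(true_times / interval)
    snapped[snapped > horizon + 1e-9] = np.nan
    return snapped


def generate_division_tracks(config: TimingConfig) -> list[SingleCellTrack]:
    """Simulate one division-tracking experiment.

    For each well: first division at g0_exit + cycle_transit, second at an
    independent additional cycle_transit.  A Bernoulli death (uniform death
    time before the first division) voids both events.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tracks: list[SingleCellTrack] = []
    for subtype in sorted(config.timing):
        t = config.timing[subtype]
        n = config.n_wells_per_subtype
        g0 = _truncated_normal(rng, t.mean_g0_exit, t.sd_g0_exit, n)
        c1 = _truncated_normal(rng, t.mean_cycle_transit, t.sd_cycle_transit, n)
        c2 = _truncated_normal(rng, t.mean_cycle_transit, t.sd_cycle_transit, n)
        first_true = g0 + c1
        second_true = first_true + c2
        died = rng.random(n) < config.death_probability
        first_obs = _snap_up(first_true, config.observation_interval, config.horizon)
        second_obs = _snap_up(second_true, config.observation_interval, config.horizon)
        for i in range(n):
            if died[i]:
                f_i = s_i = None
            else:
                f_i = None if np.isnan(first_obs[i]) else float(first_obs[i])
                s_i = None if np.isnan(second_obs[i]) else float(second_obs[i])
                if f_i is None:
                    s_i = None  # a second division cannot be seen without the first
            tracks.append(
                SingleCellTrack(
                    well_id=f"{subtype}-{i:04d}",
                    subtype=subtype,
                    first_division_time=f_i,
                    second_division_time=s_i,
                    died=bool(died[i]),
                    observation_interval=config.observation_interval,
                    horizon=config.horizon,
                )
            )
    return tracks


def tracks_to_frame(tracks: list[SingleCellTrack]) -> pd.DataFrame:
    """Tabulate tracks, one row per well (NaN = censored / dead)."""
    return pd.DataFrame(
        {
            "well_id": [t.well_id for t in tracks],
            "subtype": [t.subtype for t in tracks],
            "died": [t.died for t in tracks],
            "first_division_time": [
                np.nan if t.first_division_time is None else t.first_division_time
                for t in tracks
            ],
            "second_division_time": [
                np.nan if t.second_division_time is None else t.second_division_time
                for t in tracks
            ],
            "observation_interval": [t.observation_interval for t in tracks],
            "horizon": [t.horizon for t in tracks],
        }
    )


def frame_to_tracks(frame: pd.DataFrame) -> list[SingleCellTrack]:
    """Inverse of :func:`tracks_to_frame` (accepts real data in the same schema)."""
    tracks = []
    for row in frame.itertuples(index=False):
        first = None if pd.isna(row.first_division_time) else float(row.first_division_time)
        second = None if pd.isna(row.second_division_time) else float(row.second_division_time)
        tracks.append(
            SingleCellTrack(
                well_id=str(row.well_id),
                subtype=str(row.subtype),
                first_division_time=first,
                second_division_time=second,
                died=bool(row.died),
                observation_interval=float(row.observation_interval),
                horizon=float(row.horizon),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# BrdU incorporation time courses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BrdUConfig:
    """Design of a BrdU labelling time course.

    The noiseless labelled fraction follows ``plateau * (1 - 2**(-t/Td))``
    so the half-time of the curve is the population doubling time ``Td`` by
    construction.  Defaults give an LT/ST doubling-time ratio of 1.7
    (102 hr vs 60 hr).
    """

    doubling_time: dict = field(default_factory=lambda: {LT: 102.0, ST: 60.0})
    plateau: float = 0.95
    sampling_days: tuple = tuple(range(13))
    replicates: int = 3
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if any(td <= 0 for td in self.doubling_time.values()):
            raise ValueError("doubling_time must be positive")
        if not 0.0 < self.plateau <= 1.0:
            raise ValueError("plateau must be in (0, 1]")
        if len(self.sampling_days) == 0:
            raise ValueError("sampling_days must not be empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicates <= 0:
            raise ValueError("replicates must be positive")


def brdu_expectation(t_hours: np.ndarray, doubling_time: float, plateau: float) -> np.ndarray:
    """Expected labelled fraction at time t (hours): plateau*(1 - 2^(-t/Td))."""
    return plateau * (1.0 - np.power(2.0, -np.asarray(t_hours, dtype=float) / doubling_time))


def generate_brdu_series(config: BrdUConfig) -> pd.DataFrame:
    """Simulate labelled fractions per (subtype, day, replicate).

    Additive Gaussian noise, clipped so fractions stay in [0, 1];
    deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for subtype in sorted(config.doubling_time):
        td = config.doubling_time[subtype]
        for day in config.sampling_days:
            mu = float(brdu_expectation(np.array([day * 24.0]), td, config.plateau)[0])
            for rep in range(config.replicates):
                frac = mu + rng.normal(0.0, config.noise_sd) if config.noise_sd else mu
                rows.append(
                    {
                        "subtype": subtype,
                        "day": float(day),
                        "replicate": rep,
                        "fraction_labelled": float(np.clip(frac, 0.0, 1.0)),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Limiting-dilution engraftment tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LDADesign:
    """Design of a limiting-dilution transplantation assay."""

    doses: tuple = (50, 100, 200, 400)
    recipients_per_dose: tuple = (5, 5, 5, 5)
    true_frequency: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive")
        if len(self.recipients_per_dose) != len(self.doses):
            raise ValueError("recipients_per_dose must match doses")
        if any(n <= 0 for n in self.recipients_per_dose):
            raise ValueError("recipient counts must be positive")
        if not 0.0 <= self.true_frequency <= 1.0:
            raise ValueError("true_frequency must be in [0, 1]")


def generate_lda_counts(design: LDADesign, group: str = "group") -> pd.DataFrame:
    """Simulate engraftment counts under the single-hit Poisson model.

    Each recipient of dose d engrafts independently with probability
    1 - exp(-d * true_frequency).  Deterministic given ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    rows = []
    for dose, n in zip(design.doses, design.recipients_per_dose):
        p = 1.0 - np.exp(-dose * design.true_frequency)
        rows.append(
            {
                "dose": float(dose),
                "n_recipients": int(n),
                "n_engrafted": int(rng.binomial(n, p)),
                "group": group,
            }
        )
    return pd.DataFrame(rows)


def timing_config_with_seed(config: TimingConfig, seed: int) -> TimingConfig:
    """Convenience: the same design with a different seed."""
    return replace(config, seed=seed)
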