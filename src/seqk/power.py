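"""Monte-Carlo calibration and power estimation for the T_sum test.

The null distribution of T_sum is built by simulating background-only
pairs; the significance threshold t is the empirical 95th percentile
(higher-interpolation order statistic).  Power is the fraction of
foreground replicates whose T_sum reaches t:

    P = N_{T_sum >= t} / n_reps.

Each grid point of a power curve gets its own null calibration, and every
source of randomness descends from one master seed, so a whole table is
reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kmers import InvalidParameterError
from .simulate import ForegroundConfig, generate_pair
from .stats import StatisticKind
from .tsum import CutScheme, tsum_statistic

__all__ = [
    "PowerConfig",
    "NullDistribution",
    "PowerEstimate",
    "ConfigMismatchError",
    "TooFewReplicatesError",
    "null_threshold",
    "estimate_power",
    "power_curve",
    "curve_table",
]

SIGNIFICANCE_LEVEL = 0.05  # threshold at the 95th null percentile
DEFAULT_LENGTH = 2000
DEFAULT_N_REPS = 1000
DEFAULT_N_NULL = 1000


class ConfigMismatchError(ValueError):
    """Null calibration and power run use different test configurations."""


class TooFewReplicatesError(ValueError):
    """Not enough replicates for a stable percentile."""


@dataclass(frozen=True)
class PowerConfig:
    """Complete specification of one simulation condition."""

    length: int = DEFAULT_LENGTH
    scheme: CutScheme = field(default_factory=lambda: CutScheme(Q=1500, W=500))
    k: int = 6
    kind: StatisticKind = StatisticKind.D2S
    foreground: ForegroundConfig = field(
        default_factory=lambda: ForegroundConfig(L=8)
    )

    def null_fingerprint(self) -> tuple:
        """The fields that determine the null distribution of T_sum."""
        return (
            self.length,
            self.scheme.Q,
            self.scheme.W,
            self.k,
            StatisticKind(self.kind).value,
        )


@dataclass(frozen=True)
class NullDistribution:
    """Sorted null T_sum sample and its 95th-percentile threshold."""

    statistics: np.ndarray
    threshold: float
    n_null: int
    fingerprint: tuple


@dataclass(frozen=True)
class PowerEstimate:
    """One Monte-Carlo power estimate P = n_significant / n_reps."""

    config: PowerConfig
    threshold: float
    n_reps: int
    n_significant: int
    seed: int

    @property
    def power(self) -> float:
        return self.n_significant / self.n_reps


def _replicate_seeds(master_seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


def _tsum_replicates(
    config: PowerConfig, n: int, null: bool, master_seed: int
) -> np.ndarray:
    stats = np.empty(n)
    for i, rng in enumerate(_replicate_seeds(master_seed, n)):
        pair = generate_pair(config.length, config.foreground, null=null, seed=rng)
        res = tsum_statistic(
            pair.x, pair.y, config.scheme, config.k, config.kind
        )
        stats[i] = res.tsum
    return stats


def empirical_threshold(statistics: np.ndarray, level: float = SIGNIFICANCE_LEVEL) -> float:
    """Upper (1−level) percentile under the higher-interpolation convention."""
    return float(np.percentile(statistics, 100 * (1 - level), method="higher"))


def null_threshold(
    config: PowerConfig, n_null: int, seed: int
) -> NullDistribution:
    """Simulate ``n_null`` background pairs and take the 95th percentile."""
    if n_null < 20:
        raise TooFewReplicatesError(
            f"n_null={n_null} is too few for a 95th percentile (need >= 20)"
        )
    stats = np.sort(_tsum_replicates(config, n_null, null=True, master_seed=seed))
    return NullDistribution(
        statistics=stats,
        threshold=empirical_threshold(stats),
        n_null=n_null,
        fingerprint=config.null_fingerprint(),
    )


def estimate_power(
    config: PowerConfig,
    null: NullDistribution,
    n_reps: int,
    seed: int,
) -> PowerEstimate:
    """Fraction of foreground replicates with T_sum at or above threshold."""
    if null.fingerprint != config.null_fingerprint():
        raise ConfigMismatchError(
            f"null calibrated for {null.fingerprint}, "
            f"power requested for {config.null_fingerprint()}"
        )
    stats = _tsum_replicates(config, n_reps, null=False, master_seed=seed)
    n_sig = int((stats >= null.threshold).sum())
    return PowerEstimate(
        config=config,
        threshold=null.threshold,
        n_reps=n_reps,
        n_significant=n_sig,
        seed=seed,
    )


def power_point(
    config: PowerConfig, n_reps: int, n_null: int, seed: int
) -> PowerEstimate:
    """Calibrate a null and estimate power for a single condition."""
    ss = np.random.SeedSequence(seed)
    null_seed, fg_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    null = null_threshold(config, n_null, null_seed)
    return estimate_power(config, null, n_reps, fg_seed)


def power_curve(
    grid: list[PowerConfig],
    n_reps: int = DEFAULT_N_REPS,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
) -> list[PowerEstimate]:
    """One power estimate per grid point, each with its own null calibration.

    Point i uses master seed + i, so a one-point grid reproduces a direct
    :func:`power_point` call with the same seed.
    """
    return [
        power_point(cfg, n_reps, n_null, seed + i) for i, cfg in enumerate(grid)
    ]


def curve_table(estimates: list[PowerEstimate]) -> pd.DataFrame:
    """Tidy results table: one row per grid point."""
    rows = []
    for est in estimates:
        cfg = est.config
        rows.append(
            {
                "length": cfg.length,
                "Q": cfg.scheme.Q,
                "W": cfg.scheme.W,
                "T": cfg.scheme.T,
                "r": cfg.scheme.coverage,
                "k": cfg.k,
                "kind": StatisticKind(cfg.kind).value,
                "L": cfg.foreground.L,
                "implant_prob": cfg.foreground.implant_prob,
                "n_reps": est.n_reps,
                "n_significant": est.n_significant,
                "threshold": est.threshold,
                "power": est.power,
                "seed": est.seed,
            }
        )
    return pd.DataFrame(rows)


def sweep(
    base: PowerConfig, parameter: str, values: list
) -> list[PowerConfig]:
    """Grid varying one of {r, k, T, L, implant_prob, length} from ``base``.

    ``r`` varies coverage at fixed period T; ``T`` varies the period at
    fixed coverage.
    """
    grid = []
    for v in values:
        if parameter == "r":
            grid.append(
                replace(base, scheme=CutScheme.from_coverage(base.scheme.T, v))
            )
        elif parameter == "T":
            grid.append(
                replace(
                    base,
                    scheme=CutScheme.from_coverage(int(v), base.scheme.coverage),
                )
            )
        elif parameter == "k":
            grid.append(replace(base, k=int(v)))
        elif parameter == "L":
            grid.append(
                replace(base, foreground=replace(base.foreground, L=int(v)))
            )
        elif parameter == "implant_prob":
            grid.append(
                replace(
                    base,
                    foreground=replace(base.foreground, implant_prob=float(v)),
                )
            )
        elif parameter == "length":
            grid.append(replace(base, length=int(v)))
        else:
            raise InvalidParameterError(f"unknown sweep parameter {parameter!r}")
    return grid
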