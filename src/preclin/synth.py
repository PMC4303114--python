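"""Synthetic data generators with known ground truth.

Three simulators mirror the three experimental data types of a preclinical
endocrine-resistance study:

* **Dose matrices** -- quadruplicate growth readouts on a two-drug factorial
  grid (6x6 by default).  Monotherapy effects follow Hill curves on the
  inhibited-fraction scale; the no-interaction baseline for combinations is
  Bliss independence (surviving fractions multiply), with a signed
  interaction term ``gamma`` added on the inhibition scale where both doses
  are positive.  An alternative ``highest_single_agent`` null sets each
  combination equal to its better constituent -- the least-favorable null
  of the Min test -- for level calibration studies.
* **Expression matrices** -- genes x samples with two groups and an
  embedded up/down differential signature of known size and effect.
* **Tumor trajectories** -- exponential growth or regression with
  log-normal measurement noise on a fixed measurement grid and follow-up
  horizon, mimicking xenograft volume series.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .growth import DoseMatrixData
from .survival import TumorTrajectory

__all__ = [
    "ComboSimConfig",
    "ExprSimConfig",
    "TrajSimConfig",
    "ExpressionSim",
    "simulate_dose_matrix",
    "simulate_expression",
    "simulate_trajectories",
    "hill_inhibition",
    "expected_growth_surface",
]


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComboSimConfig:
    """Two-drug dose-matrix simulation settings.

    Doses are in arbitrary concentration units; the first dose of each axis
    must be 0 (single-agent row/column and the backdrop-alone reference).
    Hill parameters are on the inhibited-fraction scale: ``emax`` in [0, 1]
    is the maximal fraction of growth inhibited, ``ec50`` the
    half-effective dose and ``hill`` the slope.  ``interaction`` (gamma) is
    added to the Bliss-composite inhibited fraction wherever both doses are
    positive (then clipped to [0, 1]): 0 is the Bliss null, positive values
    enhancement, negative attenuation.  Replicate noise is Gaussian on the
    growth-fraction scale, truncated below at 0.
    """

    doses_a: tuple[float, ...] = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0)
    doses_b: tuple[float, ...] = (0.0, 0.1, 0.3, 1.0, 3.0, 10.0)
    emax_a: float = 0.8
    ec50_a: float = 1.0
    hill_a: float = 1.0
    emax_b: float = 0.8
    ec50_b: float = 1.0
    hill_b: float = 1.0
    interaction: float = 0.0
    noise_sd: float = 0.05
    n_reps: int = 4
    seed: int = 0
    null_mode: str = "bliss"  # or "highest_single_agent"
    backdrop: str = "ED"
    pten: str = "-Dox"
    day_n: int = 6

    def __post_init__(self) -> None:
        for name in ("doses_a", "doses_b"):
            doses = np.asarray(getattr(self, name), dtype=float)
            if len(doses) < 2:
                raise ConfigError(f"{name}: need at least two doses")
            if doses[0] != 0:
                raise ConfigError(f"{name}: first dose must be 0")
            if not np.all(np.diff(doses) > 0):
                raise ConfigError(f"{name}: doses must be strictly increasing")
        for name in ("emax_a", "emax_b"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name}: must be in [0, 1]")
        for name in ("ec50_a", "ec50_b", "hill_a", "hill_b"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd: must be non-negative")
        if self.n_reps < 2:
            raise ConfigError("n_reps: need at least 2 replicates")
        if self.null_mode not in ("bliss", "highest_single_agent"):
            raise ConfigError(f"null_mode: unknown mode {self.null_mode!r}")


@dataclass(frozen=True)
class ExprSimConfig:
    """Two-group expression matrix with an embedded up/down signature.

    ``effect`` is the mean log2-scale shift applied to embedded genes in
    group 2 (up genes +effect, down genes -effect); ``noise_sd`` the
    per-gene, per-sample Gaussian noise SD on the same scale.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 5
    n_up: int = 50
    n_down: int = 50
    effect: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    group_labels: tuple[str, str] = ("WT", "KD")

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes: must be positive")
        if self.n_samples_per_group < 2:
            raise ConfigError("n_samples_per_group: need at least 2")
        if self.n_up < 0 or self.n_down < 0:
            raise ConfigError("n_up/n_down: must be non-negative")
        if self.n_up + self.n_down > self.n_genes:
            raise ConfigError("n_up + n_down exceeds n_genes")
        if self.effect < 0:
            raise ConfigError("effect: must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd: must be positive")


@dataclass(frozen=True)
class TrajSimConfig:
    """Exponential tumor-volume trajectories with log-normal noise.

    ``rate`` is the per-day exponential rate (negative for regression,
    e.g. ``-ln(2)/25`` for a 25-day half-life); ``noise_cv`` the
    coefficient of variation of multiplicative measurement noise.  Volumes
    are measured every ``measure_interval_days`` from randomization (day 0,
    noise-free baseline) up to ``horizon_days``.
    """

    n_subjects: int = 10
    baseline_vol: float = 200.0
    rate: float = -np.log(2) / 25.0
    noise_cv: float = 0.1
    horizon_days: float = 470.0
    measure_interval_days: float = 7.0
    seed: int = 0
    arm: str = "arm"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects: must be positive")
        if self.baseline_vol <= 0:
            raise ConfigError("baseline_vol: must be positive")
        if self.horizon_days <= 0:
            raise ConfigError("horizon_days: must be positive")
        if self.measure_interval_days <= 0:
            raise ConfigError("measure_interval_days: must be positive")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv: must be non-negative")


# ---------------------------------------------------------------------------
# dose matrices
# ---------------------------------------------------------------------------

def hill_inhibition(dose, emax: float, ec50: float, hill: float):
    """Hill-curve inhibited fraction: emax * d^h / (ec50^h + d^h); 0 at d=0."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(d > 0, emax * d**hill / (ec50**hill + d**hill), 0.0)
    return frac


def expected_growth_surface(cfg: ComboSimConfig) -> pd.DataFrame:
    """Noise-free expected growth fraction per (doseA, doseB) cell.

    Single-agent growth fractions are ``1 - hill``; combinations compose by
    Bliss independence (product of growth fractions) with the interaction
    gamma added on the inhibition scale and clipped to [0, 1].  Under the
    ``highest_single_agent`` null every combination equals its more
    effective constituent instead.
    """
    ga = 1.0 - hill_inhibition(cfg.doses_a, cfg.emax_a, cfg.ec50_a, cfg.hill_a)
    gb = 1.0 - hill_inhibition(cfg.doses_b, cfg.emax_b, cfg.ec50_b, cfg.hill_b)
    A, B = np.meshgrid(ga, gb, indexing="ij")
    if cfg.null_mode == "highest_single_agent":
        surface = np.minimum(A, B)
    else:
        surface = A * B
        both = np.outer(np.asarray(cfg.doses_a) > 0, np.asarray(cfg.doses_b) > 0)
        inh = np.clip(1.0 - surface + cfg.interaction, 0.0, 1.0)
        surface = np.where(both, 1.0 - inh, surface)
    da, db = np.meshgrid(cfg.doses_a, cfg.doses_b, indexing="ij")
    return pd.DataFrame(
        {
            "drugA_dose": da.ravel(),
            "drugB_dose": db.ravel(),
            "growth_fraction": surface.ravel(),
        }
    )


#: day-0 readout and backdrop-alone readout delta used to encode growth
#: fractions as plate-style OD readouts
_DAY0_READOUT = 0.2
_CONTROL_DELTA = 0.8


def simulate_dose_matrix(cfg: ComboSimConfig) -> DoseMatrixData:
    """Simulate replicate readouts for one dose matrix.

    Each cell's expected growth fraction comes from
    :func:`expected_growth_surface`; replicates add i.i.d. Gaussian noise
    (SD ``noise_sd``) truncated below at 0.  Growth fractions are encoded
    as day-0/day-n readout pairs such that normalising against the (0, 0)
    backdrop cell recovers them: the backdrop cell has expected relative
    growth 100%.
    """
    rng = np.random.default_rng(cfg.seed)
    surface = expected_growth_surface(cfg)
    n_cells = len(surface)
    expected = np.repeat(surface["growth_fraction"].to_numpy(), cfg.n_reps)
    noise = rng.normal(0.0, cfg.noise_sd, size=n_cells * cfg.n_reps)
    growth = np.maximum(expected + noise, 0.0)
    df = pd.DataFrame(
        {
            "drugA_dose": np.repeat(surface["drugA_dose"].to_numpy(), cfg.n_reps),
            "drugB_dose": np.repeat(surface["drugB_dose"].to_numpy(), cfg.n_reps),
            "replicate": np.tile(np.arange(1, cfg.n_reps + 1), n_cells),
            "day0": _DAY0_READOUT,
            "dayN": _DAY0_READOUT + growth * _CONTROL_DELTA,
        }
    )
    return DoseMatrixData(
        df=df, backdrop=cfg.backdrop, pten=cfg.pten, day_n=cfg.day_n
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

class ExpressionSim(NamedTuple):
    """Simulated expression data with its ground-truth signature."""

    expr: pd.DataFrame          # genes x samples, log2 scale
    groups: pd.Series           # sample -> group label
    up_genes: frozenset[str]
    down_genes: frozenset[str]


def simulate_expression(cfg: ExprSimConfig) -> ExpressionSim:
    """Simulate a two-group log2 expression matrix with embedded signature.

    Per-gene baseline means are drawn once (N(8, 2) on log2 scale); samples
    add N(0, ``noise_sd``) noise.  In group 2 the first ``n_up`` genes are
    shifted +``effect`` and the next ``n_down`` genes -``effect``.  Returns
    the matrix, group labels, and the true up/down gene sets.
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_genes, cfg.n_samples_per_group
    genes = [f"G{i:05d}" for i in range(n)]
    samples = [f"{cfg.group_labels[0]}_{j + 1}" for j in range(m)] + [
        f"{cfg.group_labels[1]}_{j + 1}" for j in range(m)
    ]
    groups = pd.Series(
        [cfg.group_labels[0]] * m + [cfg.group_labels[1]] * m,
        index=samples,
        name="group",
    )
    baseline = rng.normal(8.0, 2.0, size=n)
    expr = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n, 2 * m))
    shift = np.zeros(n)
    shift[: cfg.n_up] = cfg.effect
    shift[cfg.n_up : cfg.n_up + cfg.n_down] = -cfg.effect
    expr[:, m:] += shift[:, None]
    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                          columns=samples)
    return ExpressionSim(
        expr=matrix,
        groups=groups,
        up_genes=frozenset(genes[: cfg.n_up]),
        down_genes=frozenset(genes[cfg.n_up : cfg.n_up + cfg.n_down]),
    )


# ---------------------------------------------------------------------------
# tumor trajectories
# ---------------------------------------------------------------------------

def simulate_trajectories(cfg: TrajSimConfig) -> list[TumorTrajectory]:
    """Simulate exponential tumor-volume trajectories.

    V(t) = baseline * exp(rate * t) * eps, with eps log-normal such that
    its coefficient of variation is ``noise_cv`` and E[eps] = 1.  The day-0
    baseline is recorded noise-free (it defines the randomization volume).
    """
    rng = np.random.default_rng(cfg.seed)
    days = np.arange(0.0, cfg.horizon_days + 1e-9, cfg.measure_interval_days)
    sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
    out: list[TumorTrajectory] = []
    for i in range(cfg.n_subjects):
        noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=len(days)))
        noise[0] = 1.0
        vols = cfg.baseline_vol * np.exp(cfg.rate * days) * noise
        out.append(
            TumorTrajectory(
                subject=f"{cfg.arm}_{i + 1:02d}",
                arm=cfg.arm,
                days=days.copy(),
                volumes=vols,
            )
        )
    return out
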