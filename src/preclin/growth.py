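"""Relative cell growth and growth inhibition on two-drug dose matrices.

Raw readouts (cell counts or OD) measured at day 0 and day *n* are turned
into relative growth against a reference condition::

    relative growth % = (dayN - day0)_treated / mean(dayN - day0)_reference x 100

For drug-interaction analysis the reference is the endocrine backdrop alone
-- the (0, 0) cell of the dose matrix -- which therefore has an inhibition
rate of 0.  Growth inhibition is 100 minus mean relative growth; negative
inhibition (stimulation relative to the backdrop) is preserved in the data
model and only floored at zero when a heatmap is rendered.  For display the
inhibition surface is scaled so its maximum is exactly 100% by dividing by
the maximum inhibition.

Replicate-level relative growth is retained throughout so that downstream
significance testing can use within-cell variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateControlError,
    InputError,
    ScalingUndefinedError,
    StructuralError,
)

#: canonical long-format columns for replicate dose-matrix readouts
DOSE_COLUMNS = ["drugA_dose", "drugB_dose", "replicate", "day0", "dayN"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DoseMatrixData:
    """Replicate growth readouts on a two-drug dose grid.

    Parameters
    ----------
    df
        Long-format table with columns ``drugA_dose``, ``drugB_dose``,
        ``replicate``, ``day0``, ``dayN``.  Doses of 0 encode the
        single-agent rows/columns; the (0, 0) cell is the endocrine
        backdrop alone.
    backdrop
        Endocrine condition label: ``E2``, ``ED``, ``Tam`` or ``Ful``.
    pten
        PTEN knockdown condition label (``-Dox`` or ``+Dox``).
    day_n
        Day of the final readout.
    """

    df: pd.DataFrame
    backdrop: str = "ED"
    pten: str = "-Dox"
    day_n: int = 6

    def __post_init__(self) -> None:
        missing = [c for c in DOSE_COLUMNS if c not in self.df.columns]
        if missing:
            raise InputError(f"dose matrix missing columns: {missing}")
        df = self.df
        if len(df) == 0:
            raise InputError("dose matrix has no rows")
        if (df["day0"] < 0).any() or (df["dayN"] < 0).any():
            raise InputError("readouts must be non-negative")
        if df.duplicated(["drugA_dose", "drugB_dose", "replicate"]).any():
            raise StructuralError("duplicate (doseA, doseB, replicate) rows")
        zero = (df["drugA_dose"] == 0) & (df["drugB_dose"] == 0)
        if not zero.any():
            raise StructuralError("no (0, 0) backdrop-alone reference cell")

    @property
    def cells(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.df.groupby(["drugA_dose", "drugB_dose"], sort=True)

    def replicate_pairs(self, dose_a: float, dose_b: float) -> pd.DataFrame:
        """Return the (day0, dayN) replicate rows of one cell."""
        sel = (self.df["drugA_dose"] == dose_a) & (self.df["drugB_dose"] == dose_b)
        if not sel.any():
            raise StructuralError(
                f"no cell at doseA={dose_a}, doseB={dose_b}"
            )
        return self.df.loc[sel, ["day0", "dayN"]]


@dataclass
class GrowthMatrix:
    """Per-replicate relative growth (%) on the dose grid.

    ``replicates`` holds long-format columns ``drugA_dose``, ``drugB_dose``,
    ``replicate``, ``growth_pct``; ``reference`` is the (doseA, doseB) cell
    whose mean readout delta was the normalisation denominator.
    """

    replicates: pd.DataFrame
    reference: tuple[float, float]
    control_delta: float
    cell_means: pd.DataFrame | None = None
    backdrop: str = "ED"
    pten: str = "-Dox"

    def cell_growth(self, dose_a: float, dose_b: float) -> np.ndarray:
        sel = (self.replicates["drugA_dose"] == dose_a) & (
            self.replicates["drugB_dose"] == dose_b
        )
        if not sel.any():
            raise StructuralError(f"no cell at doseA={dose_a}, doseB={dose_b}")
        return self.replicates.loc[sel, "growth_pct"].to_numpy()

    def means(self) -> pd.DataFrame:
        """Per-cell mean relative growth (%).

        Computed as mean readout delta over the control delta (ratio of
        means), so the self-normalised reference cell is exactly 100%.
        """
        if self.cell_means is not None:
            return self.cell_means
        return (
            self.replicates.groupby(["drugA_dose", "drugB_dose"], sort=True)[
                "growth_pct"
            ]
            .mean()
            .rename("mean_growth_pct")
            .reset_index()
        )

    def pivot(self) -> pd.DataFrame:
        """Mean growth as a doseA x doseB matrix (rows = drug A doses)."""
        return self.means().pivot(
            index="drugA_dose", columns="drugB_dose", values="mean_growth_pct"
        )


@dataclass
class InhibitionMatrix:
    """Per-cell mean growth inhibition (%), optionally display-scaled.

    ``df`` has columns ``drugA_dose``, ``drugB_dose``, ``inhibition_pct``
    and, after :func:`scale_for_heatmap`, ``scaled_pct``.  ``max_inhibition``
    records the scaling divisor.  Negative inhibition (growth stimulation)
    is preserved; rendering floors it at zero.
    """

    df: pd.DataFrame
    reference: tuple[float, float]
    max_inhibition: float | None = None

    @property
    def scaled(self) -> bool:
        return "scaled_pct" in self.df.columns

    def pivot(self, scaled: bool = False) -> pd.DataFrame:
        col = "scaled_pct" if scaled else "inhibition_pct"
        if scaled and not self.scaled:
            raise InputError("matrix has not been scaled; call scale_for_heatmap")
        return self.df.pivot(
            index="drugA_dose", columns="drugB_dose", values=col
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def relative_growth(
    day0,
    day_n,
    control_mean_delta: float,
):
    """Relative growth (%) of treated readouts against a control delta.

    Implements ``(dayN - day0)_treated / (dayN - day0)_control x 100`` with
    the control delta taken as the mean across the control replicates.
    Accepts scalars or arrays for the treated readouts.
    """
    if control_mean_delta == 0:
        raise DegenerateControlError(
            "control mean delta is zero; relative growth undefined"
        )
    return (np.asarray(day_n, dtype=float) - np.asarray(day0, dtype=float)) / (
        control_mean_delta
    ) * 100.0


def growth_matrix(
    data: DoseMatrixData,
    reference: tuple[float, float] = (0.0, 0.0),
    control_delta: float | None = None,
) -> GrowthMatrix:
    """Convert replicate readouts to relative growth against a reference.

    Parameters
    ----------
    data
        Replicate dose-matrix readouts.
    reference
        (doseA, doseB) cell whose mean readout delta is the normalisation
        control.  Defaults to the backdrop-alone (0, 0) cell, which the
        interaction analysis requires.
    control_delta
        External control delta (e.g. the estrogen condition run alongside
        the matrix).  Overrides ``reference`` as the denominator while the
        reference label is kept for bookkeeping.
    """
    deltas = (data.df["dayN"] - data.df["day0"]).rename("delta")
    mean_deltas = (
        pd.concat([data.df[["drugA_dose", "drugB_dose"]], deltas], axis=1)
        .groupby(["drugA_dose", "drugB_dose"], sort=True)["delta"]
        .mean()
    )
    if control_delta is None:
        key = (float(reference[0]), float(reference[1]))
        if key not in mean_deltas.index:
            raise StructuralError(
                f"no cell at doseA={key[0]}, doseB={key[1]}"
            )
        # same summation path as the per-cell means, so the reference
        # cell's mean growth is exactly 100%
        control_delta = float(mean_deltas.loc[key])
    if control_delta == 0:
        raise DegenerateControlError(
            "control mean delta is zero; relative growth undefined"
        )
    reps = data.df[["drugA_dose", "drugB_dose", "replicate"]].copy()
    reps["growth_pct"] = relative_growth(
        data.df["day0"].to_numpy(), data.df["dayN"].to_numpy(), control_delta
    )
    cell_means = (
        mean_deltas.div(control_delta)
        .mul(100.0)
        .rename("mean_growth_pct")
        .reset_index()
    )
    return GrowthMatrix(
        replicates=reps,
        reference=(float(reference[0]), float(reference[1])),
        control_delta=control_delta,
        cell_means=cell_means,
        backdrop=data.backdrop,
        pten=data.pten,
    )


def inhibition_matrix(g: GrowthMatrix) -> InhibitionMatrix:
    """Per-cell growth inhibition: 100 minus mean relative growth (%).

    The matrix must be normalised to its own (backdrop-alone) reference
    cell so that the reference has inhibition 0.  Negative inhibition is
    preserved, not clipped.
    """
    means = g.means()
    ref = (
        (means["drugA_dose"] == g.reference[0])
        & (means["drugB_dose"] == g.reference[1])
    )
    if not ref.any():
        raise StructuralError(
            f"reference cell {g.reference} absent from growth matrix"
        )
    out = means[["drugA_dose", "drugB_dose"]].copy()
    out["inhibition_pct"] = 100.0 - means["mean_growth_pct"]
    return InhibitionMatrix(df=out, reference=g.reference)


def scale_for_heatmap(i: InhibitionMatrix) -> InhibitionMatrix:
    """Scale inhibition so the maximum is exactly 100%.

    Divides by the maximum inhibition, so values never exceed 100%.
    Requires at least one positive inhibition; idempotent (the maximum of
    an already-scaled matrix is 100, and dividing by 100 x 100 is the
    identity).
    """
    values = i.df["scaled_pct"] if i.scaled else i.df["inhibition_pct"]
    max_inh = float(values.max())
    if max_inh <= 0:
        raise ScalingUndefinedError(
            "no positive inhibition anywhere in the matrix; scaling undefined"
        )
    df = i.df.copy()
    df["scaled_pct"] = values / max_inh * 100.0
    return InhibitionMatrix(df=df, reference=i.reference, max_inhibition=max_inh)
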