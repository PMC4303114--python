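"""File formats, run configuration, and the end-to-end combo pipeline.

All on-disk formats are plain text so results can be inspected without
this package: long CSV for dose matrices and trajectories, TSV with a
two-line header (sample ids, group labels) for expression, GMT for gene
signatures (two lines per signature, ``NAME_UP`` and ``NAME_DN``), JSON
for summaries and the run manifest.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, InputError, ParseError, StructuralError
from .growth import (
    DOSE_COLUMNS,
    DoseMatrixData,
    GrowthMatrix,
    InhibitionMatrix,
    growth_matrix,
    inhibition_matrix,
    scale_for_heatmap,
)
from .mintest import MatrixSummary, MinTestResult, analyze_matrix, summarize_matrix
from .signature import Signature
from .survival import TumorTrajectory

__all__ = [
    "read_dose_csv",
    "write_dose_csv",
    "write_growth_csv",
    "write_inhibition_csv",
    "write_heatmap_csv",
    "write_heatmap_png",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_mintest_csv",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# dose matrices
# ---------------------------------------------------------------------------

def read_dose_csv(
    path: str | Path,
    backdrop: str = "ED",
    pten: str = "-Dox",
    day_n: int = 6,
) -> DoseMatrixData:
    """Read long-format replicate readouts and validate the grid.

    Required columns: ``drugA_dose``, ``drugB_dose``, ``replicate``,
    ``day0``, ``dayN``.  Duplicate (doseA, doseB, replicate) rows and
    negative readouts are rejected with the offending line number
    (1-based, counting the header).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing}", line=1)
    for col in ("day0", "dayN"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ParseError(f"negative {col} readout", line=int(bad[0]) + 2)
    dup = df.duplicated(["drugA_dose", "drugB_dose", "replicate"])
    if dup.any():
        raise ParseError(
            "duplicate (doseA, doseB, replicate) row",
            line=int(df.index[dup][0]) + 2,
        )
    return DoseMatrixData(df=df, backdrop=backdrop, pten=pten, day_n=day_n)


def write_dose_csv(data: DoseMatrixData, path: str | Path) -> None:
    data.df.to_csv(path, index=False)


def write_growth_csv(g: GrowthMatrix, path: str | Path) -> None:
    """Replicate-level relative growth, long format."""
    g.replicates.to_csv(path, index=False)


def write_inhibition_csv(i: InhibitionMatrix, path: str | Path) -> None:
    i.df.to_csv(path, index=False)


def write_heatmap_csv(i: InhibitionMatrix, path: str | Path) -> None:
    """Display-scaled inhibition as a doseA x doseB matrix, floored at 0."""
    mat = i.pivot(scaled=True).clip(lower=0.0)
    mat.to_csv(path)


def write_heatmap_png(i: InhibitionMatrix, path: str | Path) -> None:
    """Optional PNG rendering of the scaled inhibition surface."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = i.pivot(scaled=True).clip(lower=0.0)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mat.to_numpy(), cmap="Reds", vmin=0, vmax=100, origin="lower")
    ax.set_xticks(range(mat.shape[1]), [f"{d:g}" for d in mat.columns])
    ax.set_yticks(range(mat.shape[0]), [f"{d:g}" for d in mat.index])
    ax.set_xlabel("drug B dose")
    ax.set_ylabel("drug A dose")
    fig.colorbar(im, ax=ax, label="growth inhibition (% of max)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_mintest_csv(results: list[MinTestResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "drugA_dose": r.dose_a,
                "drugB_dose": r.dose_b,
                "p_vs_A": r.p_vs_a,
                "p_vs_B": r.p_vs_b,
                "p_min": r.p_min,
                "call": r.call,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# expression + signatures
# ---------------------------------------------------------------------------

def write_expression_tsv(
    expr: pd.DataFrame, groups: pd.Series, path: str | Path
) -> None:
    """Genes x samples TSV with a two-line header (samples, then groups)."""
    groups = pd.Series(groups)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, expr.columns)) + "\n")
        fh.write(
            "group\t" + "\t".join(str(groups[c]) for c in expr.columns) + "\n"
        )
        expr.to_csv(fh, sep="\t", header=False)


def read_expression_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a two-line-header expression TSV; returns (matrix, groups)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        group_line = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene":
            raise ParseError("first header field must be 'gene'", line=1)
        if not group_line or group_line[0] != "group":
            raise ParseError("second line must be the 'group' header", line=2)
        if len(group_line) != len(header):
            raise ParseError("group header width mismatch", line=2)
        expr = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    expr.columns = header[1:]
    expr.index.name = "gene"
    groups = pd.Series(group_line[1:], index=header[1:], name="group")
    return expr, groups


def write_gmt(signatures: list[Signature], path: str | Path) -> None:
    """Write signatures as GMT: ``NAME_UP`` and ``NAME_DN`` lines."""
    with open(path, "w") as fh:
        for sig in signatures:
            for suffix, genes in (("UP", sig.up_genes), ("DN", sig.down_genes)):
                fh.write(
                    "\t".join(
                        [f"{sig.name}_{suffix}", f"{sig.name} {suffix.lower()} genes"]
                        + sorted(genes)
                    )
                    + "\n"
                )


def read_gmt(path: str | Path) -> list[Signature]:
    """Read GMT gene sets, pairing ``NAME_UP`` / ``NAME_DN`` into signatures.

    Sets without the up/down suffix convention become signatures with only
    up genes.
    """
    from gseapy.parser import read_gmt as _read_gmt  # line-oriented GMT parser

    sets = _read_gmt(str(path))
    if not sets:
        raise ParseError(f"no gene sets in {path}")
    grouped: dict[str, dict[str, set]] = {}
    for name, genes in sets.items():
        if name.endswith("_UP"):
            grouped.setdefault(name[:-3], {})["up"] = set(genes)
        elif name.endswith("_DN"):
            grouped.setdefault(name[:-3], {})["down"] = set(genes)
        else:
            grouped.setdefault(name, {})["up"] = set(genes)
    return [
        Signature(
            name=name,
            up_genes=frozenset(parts.get("up", set())),
            down_genes=frozenset(parts.get("down", set())),
        )
        for name, parts in grouped.items()
    ]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory_csv(
    trajectories: list[TumorTrajectory], path: str | Path
) -> None:
    """Long CSV: subject, arm, day, volume_mm3."""
    rows = []
    for tr in trajectories:
        for d, v in zip(tr.days, tr.volumes):
            rows.append(
                {"subject": tr.subject, "arm": tr.arm, "day": d, "volume_mm3": v}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> list[TumorTrajectory]:
    """Read trajectories from long CSV.

    Either a ``volume_mm3`` column or the caliper pair ``width_mm`` /
    ``length_mm`` (converted via the volume formula) must be present.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("subject", "day"):
        if col not in df.columns:
            raise ParseError(f"missing column {col!r}", line=1)
    if "volume_mm3" not in df.columns:
        if not {"width_mm", "length_mm"} <= set(df.columns):
            raise ParseError(
                "need volume_mm3 or width_mm + length_mm columns", line=1
            )
        df["volume_mm3"] = df["width_mm"] ** 2 * df["length_mm"] / 2.0
    if "arm" not in df.columns:
        df["arm"] = "all"
    out = []
    for (subject, arm), grp in df.groupby(["subject", "arm"], sort=True):
        grp = grp.sort_values("day")
        out.append(
            TumorTrajectory(
                subject=str(subject),
                arm=str(arm),
                days=grp["day"].to_numpy(),
                volumes=grp["volume_mm3"].to_numpy(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end combo-analysis run settings."""

    dose_csv: str | Path
    out_dir: str | Path
    reference: tuple[float, float] = (0.0, 0.0)
    alpha: float = 0.05
    attenuation: float = 0.95
    welch: bool = False
    seed: int = 0
    heatmap_png: bool = False
    backdrop: str = "ED"
    pten: str = "-Dox"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.attenuation < 1:
            raise ConfigError("attenuation must be in (0, 1)")


@dataclass
class PipelineResult:
    growth: GrowthMatrix
    inhibition: InhibitionMatrix
    scaled: InhibitionMatrix
    results: list[MinTestResult]
    summary: MatrixSummary
    manifest: dict
    out_dir: Path


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """normalize -> inhibition -> Min tests -> summary -> heatmap.

    Writes ``growth.csv``, ``inhibition.csv``, ``heatmap.csv``,
    ``mintest.csv``, ``summary.json`` and ``manifest.json`` under
    ``out_dir``.  Outputs are a pure function of the input file and the
    configuration (the manifest records versions and thresholds, never
    timestamps), so repeated runs are bit-identical.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    data = _stage("read", read_dose_csv, cfg.dose_csv, cfg.backdrop, cfg.pten)
    g = _stage("normalize", growth_matrix, data, reference=cfg.reference)
    inh = _stage("inhibition", inhibition_matrix, g)
    scaled = _stage("heatmap", scale_for_heatmap, inh)
    results = _stage(
        "mintest", analyze_matrix, g,
        alpha=cfg.alpha, attenuation=cfg.attenuation, welch=cfg.welch,
    )
    summary = _stage("summary", summarize_matrix, results)

    write_growth_csv(g, out / "growth.csv")
    write_inhibition_csv(inh, out / "inhibition.csv")
    write_heatmap_csv(scaled, out / "heatmap.csv")
    write_mintest_csv(results, out / "mintest.csv")
    summary_json = {
        "n_combinations": summary.n_combinations,
        "pct_enhanced": summary.pct_enhanced,
        "pct_attenuated": summary.pct_attenuated,
        "alpha": cfg.alpha,
        "attenuation": cfg.attenuation,
    }
    (out / "summary.json").write_text(json.dumps(summary_json, indent=2) + "\n")

    manifest = {
        "preclin_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input": Path(cfg.dose_csv).name,
        "reference": list(cfg.reference),
        "alpha": cfg.alpha,
        "attenuation": cfg.attenuation,
        "welch": cfg.welch,
        "seed": cfg.seed,
        "outputs": [
            "growth.csv", "inhibition.csv", "heatmap.csv",
            "mintest.csv", "summary.json",
        ],
    }
    if cfg.heatmap_png:
        write_heatmap_png(scaled, out / "heatmap.png")
        manifest["outputs"].append("heatmap.png")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return PipelineResult(
        growth=g, inhibition=inh, scaled=scaled,
        results=results, summary=summary, manifest=manifest, out_dir=out,
    )
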