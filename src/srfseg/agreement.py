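"""Multi-reader agreement statistics: DSC, volume and LRF% differences,
Spearman correlation and Bland-Altman analysis, with Table-style reports.

Comparisons are oriented as (first source - second source); a model-vs-reader
row therefore reports model - reader, matching the convention under which an
automatic method that slightly under-measures shows a negative bias. Dice of
two empty masks is defined as 1.0 so that two sources that correctly segment
nothing on the absent side of a solitary kidney agree perfectly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DataError, MeasurementError
from .measure import compute_srf, mask_volume_ml
from .volumes import ImageVolume, LabelVolume

__all__ = [
    "ComparisonRecord",
    "BlandAltmanResult",
    "dice",
    "bland_altman",
    "spearman",
    "compare_pair",
    "summarize",
]


@dataclass
class ComparisonRecord:
    """One ordered pairwise comparison between two segmentation sources."""

    case_id: str
    source_a: str
    source_b: str
    dsc_left: float
    dsc_right: float
    diff_vol_left_ml: float
    diff_vol_right_ml: float
    diff_lrf_ppt: float
    lrf_a: float
    lrf_b: float
    vol_left_a_ml: float = np.nan
    vol_right_a_ml: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement of paired differences."""

    bias: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice-Sorensen coefficient 2|A^B| / (|A|+|B|) of two binary masks.

    Both empty -> 1.0 (perfect agreement on absence); exactly one empty -> 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ContractError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    Differences d = x - y; bias = mean(d); limits of agreement are
    bias +- 1.96 * sd(d) with the sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ContractError(f"lengths differ: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise DataError("Bland-Altman needs at least 2 paired measurements")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=x.size)


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ContractError(f"lengths differ: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise DataError("Spearman correlation needs at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise MeasurementError("Spearman correlation undefined: zero rank variance")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def compare_pair(
    seg_a: LabelVolume,
    seg_b: LabelVolume,
    pet: ImageVolume,
    case_id: str = "case",
    source_a: str = "a",
    source_b: str = "b",
) -> ComparisonRecord:
    """Per-kidney DSC and volume difference plus the LRF% difference (a - b)."""
    if not seg_a.same_geometry(seg_b) or not seg_a.same_geometry(pet):
        raise ContractError("segmentations and PET must share geometry")
    lrf_a = compute_srf(pet, seg_a).lrf_percent
    lrf_b = compute_srf(pet, seg_b).lrf_percent
    return ComparisonRecord(
        case_id=case_id,
        source_a=source_a,
        source_b=source_b,
        dsc_left=dice(seg_a.mask(1), seg_b.mask(1)),
        dsc_right=dice(seg_a.mask(2), seg_b.mask(2)),
        diff_vol_left_ml=mask_volume_ml(seg_a, 1) - mask_volume_ml(seg_b, 1),
        diff_vol_right_ml=mask_volume_ml(seg_a, 2) - mask_volume_ml(seg_b, 2),
        diff_lrf_ppt=lrf_a - lrf_b,
        lrf_a=lrf_a,
        lrf_b=lrf_b,
        vol_left_a_ml=mask_volume_ml(seg_a, 1),
        vol_right_a_ml=mask_volume_ml(seg_a, 2),
    )


def _fmt(median: float, lo: float, hi: float) -> str:
    return f"{median:.2f} ({lo:.2f} to {hi:.2f})"


def summarize(records: list[ComparisonRecord]) -> dict:
    """Aggregate pairwise records into a per-source-pair report.

    For each (source_a, source_b) pair: median (min-max) of the per-kidney
    volume differences, DSCs and the LRF% difference, plus a Bland-Altman
    analysis of the LRF% measurements, plus Spearman matrices of LRF% and
    total renal volume across sources. Ordered duplicates (b vs a when a vs b
    exists) collapse onto the first-listed orientation.
    """
    if not records:
        raise DataError("summarize needs at least one comparison record")
    df = pd.DataFrame([r.to_dict() for r in records])

    seen, rows, ba = [], [], {}
    for (a, b), grp in df.groupby(["source_a", "source_b"], sort=False):
        if (b, a) in seen:
            continue
        seen.append((a, b))
        vols = pd.concat([grp.diff_vol_left_ml, grp.diff_vol_right_ml])
        dscs = pd.concat([grp.dsc_left, grp.dsc_right])
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "source_a": a,
                "source_b": b,
                "n_cases": len(grp),
                "diff_vol_ml": _fmt(vols.median(), vols.min(), vols.max()),
                "dsc": _fmt(dscs.median(), dscs.min(), dscs.max()),
                "diff_lrf_ppt": _fmt(
                    grp.diff_lrf_ppt.median(), grp.diff_lrf_ppt.min(), grp.diff_lrf_ppt.max()
                ),
                "dsc_median": float(dscs.median()),
                "diff_lrf_median": float(grp.diff_lrf_ppt.median()),
            }
        )
        if len(grp) >= 2:
            ba[f"{a} vs {b}"] = bland_altman(grp.lrf_a.to_numpy(), grp.lrf_b.to_numpy()).to_dict()

    table = pd.DataFrame(rows)

    # per-source measurement vectors over cases, for Spearman matrices
    lrf_wide = _source_measurements(df, "lrf")
    vol_wide = _source_measurements(df, "vol")
    spearman_lrf = _spearman_matrix(lrf_wide)
    spearman_vol = _spearman_matrix(vol_wide)

    return {
        "table": table,
        "bland_altman": ba,
        "spearman_lrf": spearman_lrf,
        "spearman_volume": spearman_vol,
    }


def _source_measurements(df: pd.DataFrame, what: str) -> pd.DataFrame:
    rows = {}
    for _, r in df.iterrows():
        val = r.lrf_a if what == "lrf" else r.vol_left_a_ml + r.vol_right_a_ml
        rows[(r.case_id, r.source_a)] = val
        if what == "lrf":
            rows.setdefault((r.case_id, r.source_b), r.lrf_b)
    s = pd.Series(rows)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["case_id", "source"])
    return s.unstack("source")


def _spearman_matrix(wide: pd.DataFrame) -> pd.DataFrame:
    sources = list(wide.columns)
    mat = pd.DataFrame(np.eye(len(sources)), index=sources, columns=sources)
    for a, b in combinations(sources, 2):
        sub = wide[[a, b]].dropna()
        try:
            rho = spearman(sub[a].to_numpy(), sub[b].to_numpy())
        except (DataError, MeasurementError):
            rho = np.nan
        mat.loc[a, b] = mat.loc[b, a] = rho
    return mat


def records_from_manifest(manifest_csv) -> list[ComparisonRecord]:
    """Build ordered pairwise records from a manifest CSV.

    Expected columns: ``case_id``, ``source``, ``path`` (mask NIfTI) and
    ``pet_path`` (one PET NIfTI per case; repeated per row is fine).
    """
    from .volumes import Modality, read_volume

    df = pd.read_csv(manifest_csv)
    required = {"case_id", "source", "path", "pet_path"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"manifest is missing columns: {sorted(missing)}")
    records = []
    for case_id, grp in df.groupby("case_id", sort=False):
        pet = read_volume(grp.pet_path.iloc[0], Modality.PET_SUV)
        masks = {row.source: read_volume(row.path, None) for row in grp.itertuples()}
        names = list(masks)
        for a in range(len(names)):
            for b in range(len(names)):
                if a != b:
                    records.append(
                        compare_pair(masks[names[a]], masks[names[b]], pet,
                                     case_id=str(case_id),
                                     source_a=names[a], source_b=names[b])
                    )
    return records


def report_to_files(report: dict, out_dir, make_plots: bool = False) -> None:
    """Write report.csv / report.json (and optional Bland-Altman figures)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table: pd.DataFrame = report["table"]
    table.to_csv(out / "report.csv", index=False)
    payload = {
        "table": table.to_dict(orient="records"),
        "bland_altman": report["bland_altman"],
        "spearman_lrf": report["spearman_lrf"].to_dict(),
        "spearman_volume": report["spearman_volume"].to_dict(),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=float))
    if make_plots:  # pragma: no cover - optional dependency
        _plot_bland_altman(report, out)


def _plot_bland_altman(report: dict, out) -> None:  # pragma: no cover
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = report["bland_altman"]
    if not ba:
        return
    fig, axes = plt.subplots(1, len(ba), figsize=(4 * len(ba), 3.2), squeeze=False)
    for ax, (pair, res) in zip(axes.ravel(), ba.items()):
        ax.axhline(res["bias"], ls="--", c="k")
        ax.axhline(res["loa_low"], ls="--", c="gray")
        ax.axhline(res["loa_high"], ls="--", c="gray")
        ax.set_title(pair)
        ax.set_xlabel("mean LRF% of pair")
        ax.set_ylabel("difference (ppt)")
    fig.tight_layout()
    fig.savefig(out / "bland_altman.png", dpi=120)
    plt.close(fig)
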