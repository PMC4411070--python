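"""CSV/JSON file formats and run manifests for the pipeline.

Everything is plain text: ponds (stratum, year, ponds), monthly climate
(stratum, year, month, precip_mm, tmax_c), geometry (stratum, x_km, y_km,
area_km2), posterior summaries (parameter, median, ci_lo, ci_hi) and
variance proportions (stratum, predictor, proportion_median, ci_lo,
ci_hi).  Each pipeline stage writes a JSON manifest carrying the seed, a
hash of the effective configuration and the sampler diagnostics, which is
sufficient to reproduce the run bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .simulate import StrataGeometry
from .spatial import DistanceMatrix

__all__ = [
    "read_pond_table",
    "write_pond_table",
    "read_geometry",
    "write_geometry",
    "read_monthly_climate",
    "write_monthly_climate",
    "config_hash",
    "write_manifest",
    "read_manifest",
]


def read_pond_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the pond CSV into a dense stratum x year pivot.

    Requires columns (stratum, year, ponds); raises named validation
    errors for duplicates, missing stratum-year cells, and nonpositive
    counts.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"stratum", "year", "ponds"} - set(df.columns)
    if missing:
        raise ValueError(f"pond table missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["stratum", "year"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate pond record for stratum {row['stratum']}, "
            f"year {int(row['year'])}"
        )
    bad = df["ponds"] <= 0
    if bad.any():
        row = df.loc[bad.idxmax()]
        raise ValueError(
            f"nonpositive pond count for stratum {row['stratum']}, "
            f"year {int(row['year'])}: {row['ponds']}"
        )
    pivot = df.pivot(index="stratum", columns="year", values="ponds")
    if pivot.isna().any().any():
        gaps = [
            f"({s}, {y})"
            for s, y in zip(*np.where(pivot.isna().to_numpy()))
        ]
        labels = [
            f"({pivot.index[int(i)]}, {pivot.columns[int(j)]})"
            for i, j in zip(*np.where(pivot.isna().to_numpy()))
        ]
        raise ValueError(
            f"pond panel has {len(gaps)} missing stratum-year cells: "
            + ", ".join(labels[:10])
        )
    return pivot.sort_index(axis=0).sort_index(axis=1)


def write_pond_table(path: str | Path, ponds: np.ndarray, strata_ids, years) -> None:
    rows = [
        {"stratum": s, "year": int(y), "ponds": ponds[i, j]}
        for i, s in enumerate(strata_ids)
        for j, y in enumerate(years)
    ]
    # 17 significant digits so float64 counts survive the text round trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_geometry(path: str | Path, geometry: StrataGeometry) -> None:
    pd.DataFrame(
        {
            "stratum": list(geometry.ids),
            "x_km": geometry.centroids[:, 0],
            "y_km": geometry.centroids[:, 1],
            "area_km2": geometry.areas,
        }
    ).to_csv(path, index=False)


def read_geometry(path: str | Path) -> StrataGeometry:
    df = pd.read_csv(path)
    missing = {"stratum", "x_km", "y_km", "area_km2"} - set(df.columns)
    if missing:
        raise ValueError(f"geometry table missing columns {sorted(missing)}")
    df = df.sort_values("stratum").reset_index(drop=True)
    centroids = df[["x_km", "y_km"]].to_numpy(dtype=float)
    return StrataGeometry(
        ids=tuple(df["stratum"].astype(str)),
        centroids=centroids,
        areas=df["area_km2"].to_numpy(dtype=float),
        D=DistanceMatrix(squareform(pdist(centroids))),
    )


def write_monthly_climate(path: str | Path, monthly: pd.DataFrame) -> None:
    monthly.to_csv(path, index=False)


def read_monthly_climate(path: str | Path) -> pd.DataFrame:
    from .design import validate_monthly

    return validate_monthly(pd.read_csv(path))


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, **extra) -> dict:
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
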