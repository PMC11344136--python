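"""Reading and writing the package's on-disk formats.

Tables are plain TSV/CSV; geometry is a documented JSON container with an
optional GIFTI export (requires nibabel); profile arrays are an ``.npz``
container with a JSON sidecar index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import SphereGeometry
from .profiles import MeasureTable, ProfileArray, parcel_columns
from .synth import COHORT_COLUMNS, validate_cohort

GEOMETRY_FORMAT_VERSION = 1


# -- geometry ---------------------------------------------------------------

def write_geometry(geom: SphereGeometry, path: str | Path) -> None:
    payload = {
        "format_version": GEOMETRY_FORMAT_VERSION,
        "is_sphere": geom.is_sphere,
        "vertex_coords": geom.vertex_coords.tolist(),
        "faces": geom.faces.tolist(),
        "parcel_labels": geom.parcel_labels.tolist(),
        "parcel_centroids": geom.parcel_centroids.tolist(),
        "parcel_hemispheres": list(geom.parcel_hemispheres),
        "vertex_hemispheres": list(geom.vertex_hemispheres),
    }
    Path(path).write_text(json.dumps(payload))


def read_geometry(path: str | Path) -> SphereGeometry:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != GEOMETRY_FORMAT_VERSION:
        raise ValueError(f"unsupported geometry format in {path}")
    return SphereGeometry(
        vertex_coords=np.asarray(payload["vertex_coords"], dtype=float),
        faces=np.asarray(payload["faces"], dtype=int),
        parcel_labels=np.asarray(payload["parcel_labels"], dtype=int),
        parcel_centroids=np.asarray(payload["parcel_centroids"], dtype=float),
        parcel_hemispheres=np.asarray(payload["parcel_hemispheres"], dtype=object),
        vertex_hemispheres=np.asarray(payload["vertex_hemispheres"], dtype=object),
        is_sphere=bool(payload["is_sphere"]),
    )


def export_gifti(geom: SphereGeometry, surf_path: str | Path,
                 label_path: str | Path) -> None:
    """Optional GIFTI surface (.surf.gii) + label (.label.gii) export."""
    import nibabel as nib

    coords = nib.gifti.GiftiDataArray(
        geom.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    faces = nib.gifti.GiftiDataArray(
        geom.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[coords, faces]), str(surf_path))
    labels = nib.gifti.GiftiDataArray(
        geom.parcel_labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[labels]), str(label_path))


# -- cohort -----------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False, columns=[c for c in COHORT_COLUMNS
                                              if c in cohort.columns]
                  + [c for c in cohort.columns if c not in COHORT_COLUMNS])


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a cohort CSV; returns (table, consistency warnings)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "family_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    if df["oc_user"].dtype != bool:
        df["oc_user"] = (
            df["oc_user"].astype(str).str.lower().isin(["true", "1", "1.0"])
        )
    return df, validate_cohort(df)


# -- profiles ---------------------------------------------------------------

def write_profiles(profiles: ProfileArray, path: str | Path) -> None:
    """Write a profile array as .npz plus a JSON index sidecar."""
    path = Path(path)
    np.savez_compressed(path, values=profiles.values,
                        depth_fractions=profiles.depth_fractions)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "subject_ids": profiles.subject_ids,
        "n_parcels": profiles.n_parcels,
        "n_depths": profiles.n_depths,
    }))


def read_profiles(path: str | Path) -> ProfileArray:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValueError(f"missing profile index sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    with np.load(path) as z:
        values = z["values"]
        depths = z["depth_fractions"]
    if values.shape != (len(meta["subject_ids"]), meta["n_parcels"],
                        meta["n_depths"]):
        raise ValueError(
            f"profile array in {path} does not match its index "
            f"(expected {len(meta['subject_ids'])} subjects)"
        )
    return ProfileArray(values=values, depth_fractions=depths,
                        subject_ids=meta["subject_ids"])


def write_subject_profile_tsv(profiles: ProfileArray, subject: str,
                              path: str | Path) -> None:
    """Per-subject TSV alternative: rows = parcels, cols = depths."""
    s = profiles.subject_ids.index(subject)
    pd.DataFrame(
        profiles.values[s],
        index=parcel_columns(profiles.n_parcels),
        columns=[f"d{k:02d}" for k in range(profiles.n_depths)],
    ).to_csv(path, sep="\t", index_label="parcel")


# -- measure tables and matrices -------------------------------------------

def write_measure(table: MeasureTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="subject_id")


def read_measure(path: str | Path, name: str) -> MeasureTable:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return MeasureTable(name=name, values=df)


def write_matrix(values: np.ndarray, path: str | Path) -> None:
    p = values.shape[0]
    pd.DataFrame(values, index=parcel_columns(p),
                 columns=parcel_columns(p)).to_csv(path, sep="\t",
                                                   index_label="parcel")


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col="parcel").to_numpy(dtype=float)


def write_contrast(result, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)
    meta = {
        "comparison": result.comparison,
        "dof": int(result.dof),
        "n1": int(result.n1),
        "n2": int(result.n2),
        "q": result.q,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))
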