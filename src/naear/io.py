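"""File formats: NIfTI volumes with JSON sidecars, delimited-text
trajectories and landmarks, the k-space container, and the bundled
reference-cohort tables.

Volumes travel as NIfTI-1 with RAS+ affines; 4D offset-sweep stacks carry
their Hz list in a JSON sidecar next to the image file.  Trajectories and
landmark pairs are plain TSV so they can be inspected and edited by hand.
K-space sets are a single ``.npz`` container whose JSON header records the
sequence parameters, phase cycles, noise level and seed.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import KSpaceSet, PhaseCycleSet, SequenceParams, Trajectory
from .phantom import PhantomVolume, Tissue
from .quantify import STRUCTURES, SIDES, LikertAssessment
from .registration import LandmarkSet

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_phantom",
    "save_trajectory",
    "load_trajectory",
    "save_kspace",
    "load_kspace",
    "save_landmarks",
    "load_landmarks",
    "bundled_table",
    "load_likert_table",
    "load_roi_table",
    "load_cohort_table",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_nifti(
    path, data: np.ndarray, affine: np.ndarray, offsets=None, extra_meta=None
) -> Path:
    """Write a 3D volume or 4D offset stack; offsets/meta go to a sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    nib.save(img, str(path))
    meta = dict(extra_meta or {})
    if offsets is not None:
        meta["frequency_offsets_hz"] = [float(o) for o in offsets]
    if meta:
        _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_nifti(path):
    """Read a NIfTI file -> (data, affine, metadata dict from sidecar)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return np.asarray(img.dataobj), img.affine, meta


def write_phantom(phantom: PhantomVolume, outdir) -> dict[str, Path]:
    """Export every phantom map as NIfTI plus a JSON label legend."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    maps = {
        "concentration": phantom.concentration_map,
        "t1": phantom.t1_map,
        "t2": phantom.t2_map,
        "t2star": phantom.t2star_map,
        "offres": phantom.offres_map,
        "labels": phantom.label_map.astype(np.int16),
    }
    for name, arr in maps.items():
        paths[name] = write_nifti(outdir / f"{name}.nii", arr, phantom.affine)
    legend = {t.name.lower(): int(t.value) for t in Tissue}
    legend_path = outdir / "label_legend.json"
    legend_path.write_text(json.dumps(legend, indent=2))
    paths["legend"] = legend_path
    return paths


def save_trajectory(path, trajectory: Trajectory) -> Path:
    path = Path(path)
    table = np.column_stack(
        [
            trajectory.coords,
            trajectory.timestamps,
            trajectory.density_weights,
        ]
    )
    header = f"kind={trajectory.kind} n_readouts={trajectory.n_readouts}\nkx\tky\tkz\tt_ms\tweight"
    np.savetxt(path, table, delimiter="\t", header=header, fmt="%.10g")
    return path


def load_trajectory(path) -> Trajectory:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().lstrip("# ").strip()
    fields = dict(kv.split("=") for kv in first.split())
    table = np.loadtxt(path, delimiter="\t", skiprows=2)
    return Trajectory(
        coords=table[:, :3],
        timestamps=table[:, 3],
        density_weights=table[:, 4],
        kind=fields.get("kind", "unknown"),
        n_readouts=int(fields.get("n_readouts", 0)),
    )


def save_kspace(path, kspace: KSpaceSet) -> Path:
    """Single-container export: arrays + JSON header (params, cycles, seed)."""
    path = Path(path)
    header = {
        "params": {
            "tr": kspace.params.tr,
            "te": kspace.params.te,
            "flip": kspace.params.flip,
            "rf_pulse_width": kspace.params.rf_pulse_width,
            "readout_duration": kspace.params.readout_duration,
            "resolution": kspace.params.resolution,
            "fov": kspace.params.fov,
            "n_phase_cycles": kspace.params.n_phase_cycles,
        },
        "cycles_deg": list(kspace.cycles.increments),
        "noise_sd": kspace.noise_sd,
        "seed": kspace.seed,
        "trajectory_kind": kspace.trajectory.kind,
        "n_readouts": kspace.trajectory.n_readouts,
        "shape": list(kspace.samples.shape),
    }
    np.savez(
        path,
        samples=kspace.samples,
        coords=kspace.trajectory.coords,
        timestamps=kspace.trajectory.timestamps,
        weights=kspace.trajectory.density_weights,
        header=np.frombuffer(json.dumps(header, sort_keys=True).encode(), dtype=np.uint8),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_kspace(path) -> KSpaceSet:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"].tobytes()).decode())
        trajectory = Trajectory(
            coords=z["coords"],
            timestamps=z["timestamps"],
            density_weights=z["weights"],
            kind=header["trajectory_kind"],
            n_readouts=int(header["n_readouts"]),
        )
        return KSpaceSet(
            trajectory=trajectory,
            samples=z["samples"],
            cycles=PhaseCycleSet(tuple(header["cycles_deg"])),
            params=SequenceParams(**header["params"]),
            noise_sd=float(header["noise_sd"]),
            seed=int(header["seed"]),
        )


def save_landmarks(path, landmarks: LandmarkSet) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("label\tfx\tfy\tfz\tmx\tmy\tmz\n")
        for lab, f, m in zip(landmarks.labels, landmarks.fixed, landmarks.moving):
            fh.write(
                f"{lab}\t{f[0]:.6f}\t{f[1]:.6f}\t{f[2]:.6f}"
                f"\t{m[0]:.6f}\t{m[1]:.6f}\t{m[2]:.6f}\n"
            )
    return path


def load_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path, sep="\t")
    required = ["label", "fx", "fy", "fz", "mx", "my", "mz"]
    if list(df.columns) != required:
        raise ValueError(f"landmark file must have columns {required}")
    return LandmarkSet(
        fixed=df[["fx", "fy", "fz"]].to_numpy(float),
        moving=df[["mx", "my", "mz"]].to_numpy(float),
        labels=tuple(df["label"].astype(str)),
    )


def bundled_table(name: str) -> Path:
    """Path to one of the packaged reference-cohort CSV tables."""
    ref = resources.files("naear") / "data" / name
    return Path(str(ref))


def load_likert_table(path=None) -> pd.DataFrame:
    """Grade table -> DataFrame; see :func:`likert_assessments` to convert."""
    path = path or bundled_table("likert_grades.csv")
    df = pd.read_csv(path, keep_default_na=False)
    return df


def likert_assessments(df: pd.DataFrame) -> list[dict]:
    """Rows of a grade table -> records with a LikertAssessment each."""
    out = []
    for row in df.itertuples():
        grades = {}
        for s in STRUCTURES:
            for d in SIDES:
                vis = int(getattr(row, f"{d}_{s}_vis"))
                comp = int(getattr(row, f"{d}_{s}_comp"))
                grades[(s, d)] = (vis, comp)
        out.append(
            {
                "participant": row.participant,
                "eh_side": getattr(row, "eh_side", None),
                "reported_certainty": getattr(row, "reported_certainty", None),
                "reported_side": getattr(row, "reported_side", None) or None,
                "assessment": LikertAssessment(
                    observer=str(row.observer),
                    timepoint=row.timepoint,
                    grades=grades,
                ),
            }
        )
    return out


def load_roi_table(path=None) -> pd.DataFrame:
    path = path or bundled_table("roi_medians.csv")
    return pd.read_csv(path)


def load_cohort_table(path=None) -> pd.DataFrame:
    path = path or bundled_table("cohort.csv")
    return pd.read_csv(path)
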