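"""File formats: NIfTI stacks with JSON echo-time sidecars, contour and
stats CSVs, parameter-map volumes, and the serialisable run configuration.

The interchange convention is deliberately minimal: a multi-echo series
is one NIfTI volume of shape (rows, cols, n_echoes) — echo dimension
last — accompanied by a JSON sidecar ``{"sequence": ..., "times_ms":
[...]}``.  Parameter maps are written as single-volume NIfTI files with
NaN encoding missing pixels and the input's spatial metadata preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import ImageStack
from .rician import ParameterMaps
from .segmentation import ContourPair
from .sequences import EchoSchedule

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_parameter_maps",
    "read_contours_csv",
    "write_contours_csv",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    Serialised as JSON next to a run's outputs.
    """

    sequence: str = "GraSE"
    times_ms: list[float] | None = None  # schedule override; None = defaults
    sigma_policy: str = "background"  # background | joint | fixed
    sigma: float | None = None
    t2_bounds: tuple[float, float] = (1.0, 500.0)
    homogeneity_threshold: float = 0.20
    seed: int = 0
    output_dir: str = "."
    exclude_inhomogeneous: bool = False
    include_first_echo: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "t2_bounds" in d and d["t2_bounds"] is not None:
            d["t2_bounds"] = tuple(d["t2_bounds"])
        return cls(**d)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def read_stack(path: str | Path, sidecar: str | Path) -> tuple[ImageStack, EchoSchedule]:
    """Load a multi-echo NIfTI stack and its echo-time sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    schedule = EchoSchedule.read_sidecar(sidecar)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[2] == 1:  # (r, c, 1, echo) also accepted
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise ValueError(f"expected a (rows, cols, echoes) image, got shape {data.shape}")
    if data.shape[2] != len(schedule):
        raise ValueError(
            f"image has {data.shape[2]} echoes but sidecar lists {len(schedule)} times"
        )
    zooms = img.header.get_zooms()[:2]
    stack = ImageStack(data, pixel_spacing_mm=(float(zooms[0]), float(zooms[1])), affine=img.affine)
    return stack, schedule


def write_stack(
    stack: ImageStack, schedule: EchoSchedule, path: str | Path, sidecar: str | Path
) -> None:
    nib.Nifti1Image(stack.data.astype(np.float64), stack.affine).to_filename(str(path))
    schedule.write_sidecar(sidecar)


def write_parameter_maps(
    maps: ParameterMaps, outdir: str | Path, affine: np.ndarray | None = None
) -> dict[str, Path]:
    """Write each parameter map as a NIfTI volume; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.eye(4)
    arrays = {
        "t2": maps.t2_map,
        "s0": maps.s0_map,
        "sigma": maps.sigma_map,
        "loglik": maps.loglik_map,
        "converged": maps.converged_mask.astype(np.uint8),
    }
    written = {}
    for name, arr in arrays.items():
        p = outdir / f"{name}.nii.gz"
        nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine).to_filename(str(p))
        written[name] = p
    return written


def write_contours_csv(contours: ContourPair, path: str | Path) -> None:
    """CSV with columns contour (endo/epi), x, y — one vertex per row."""
    frames = []
    for name, poly in (("endo", contours.endo), ("epi", contours.epi)):
        frames.append(pd.DataFrame({"contour": name, "x": poly[:, 0], "y": poly[:, 1]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> ContourPair:
    df = pd.read_csv(path)
    missing = {"contour", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"contour CSV missing columns: {sorted(missing)}")
    polys = {}
    for name, grp in df.groupby("contour"):
        polys[name] = grp[["x", "y"]].to_numpy(dtype=float)
    if set(polys) != {"endo", "epi"}:
        raise ValueError(f"contour CSV must contain endo and epi, got {sorted(polys)}")
    return ContourPair(endo=polys["endo"], epi=polys["epi"])


def write_manifest(outdir: str | Path, files: list[str | Path]) -> Path:
    """Checksummed listing of a run's outputs."""
    outdir = Path(outdir)
    entries = []
    for f in files:
        f = Path(f)
        entries.append(
            {
                "path": str(f.relative_to(outdir) if f.is_relative_to(outdir) else f),
                "sha256": hashlib.sha256(f.read_bytes()).hexdigest(),
                "bytes": f.stat().st_size,
            }
        )
    p = outdir / "manifest.json"
    p.write_text(json.dumps(entries, indent=2))
    return p
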