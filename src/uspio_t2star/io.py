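"""File formats, configuration and provenance.

Multi-echo stacks travel as 4D NIfTI (x, y, slice=1, echo) with a JSON
sidecar carrying echo times (ms), session, field strength and subject
id.  Map products are written as NIfTI volumes plus a PNG T2* colourmap
on a fixed 0-60 ms display scale, with a provenance text file (config
hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .phantom import MultiEchoImage
from .relaxometry import R2StarMap
from .tissues import (
    DEFAULT_DOSE_MG_PER_KG,
    DEFAULT_ECHO_TIMES_MS,
    DEFAULT_MIN_ECHOES,
    DEFAULT_R2_GATE,
)

T2STAR_DISPLAY_MAX_MS = 60.0  # fixed colourmap ceiling, ms


def _sidecar_path(nifti_path: Path) -> Path:
    name = nifti_path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return nifti_path.with_name(name[: -len(suffix)] + ".json")
    return nifti_path.with_suffix(".json")


def write_multiecho(image: MultiEchoImage, path: str | Path,
                    pixel_spacing_mm: tuple[float, float] = (2.0, 2.0),
                    seed: int | None = None) -> tuple[Path, Path]:
    """Write a multi-echo stack as 4D NIfTI + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # (echo, row, col) -> (x=col, y=row, slice, echo) for the NIfTI layout
    data = np.transpose(image.echo_images, (2, 1, 0))[:, :, np.newaxis, :]
    affine = np.diag([pixel_spacing_mm[1], pixel_spacing_mm[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))
    sidecar = _sidecar_path(path)
    meta = {
        "echo_times_ms": [float(t) for t in image.echo_times_ms],
        "session": image.session,
        "field_strength": image.field_strength,
        "subject_id": image.subject_id,
    }
    if seed is not None:
        meta["seed"] = int(seed)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path, sidecar


def read_multiecho(path: str | Path) -> MultiEchoImage:
    """Read a 4D NIfTI + sidecar back into a MultiEchoImage.

    Echo times are sorted ascending (with a warning, reordering the
    volumes consistently); mismatched echo counts, negative values or a
    missing sidecar raise descriptive errors.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4D NIfTI (x, y, slice, echo), got shape {data.shape}")
    te = np.asarray(meta["echo_times_ms"], dtype=float)
    if te.size != data.shape[3]:
        raise ValueError(f"sidecar lists {te.size} echo times for a "
                         f"{data.shape[3]}-volume stack")
    if np.any(data < 0):
        raise ValueError("magnitude stack contains negative values")
    stack = np.transpose(data[:, :, 0, :], (2, 1, 0))  # -> (echo, row, col)
    if np.any(np.diff(te) <= 0):
        order = np.argsort(te, kind="stable")
        if np.unique(te).size != te.size:
            raise ValueError("duplicate echo times in sidecar")
        warnings.warn("echo times were not sorted; reordering volumes", stacklevel=2)
        te, stack = te[order], stack[order]
    return MultiEchoImage(stack, te, session=meta.get("session", "pre"),
                          field_strength=float(meta.get("field_strength", 1.5)),
                          subject_id=meta.get("subject_id", "unknown"))


def _save_scalar_nifti(arr: np.ndarray, path: Path) -> None:
    data = np.transpose(np.nan_to_num(arr, nan=0.0), (1, 0))[:, :, np.newaxis]
    nib.save(nib.Nifti1Image(data.astype(np.float64), np.eye(4)), str(path))


def write_map_products(r2map: R2StarMap, outdir: str | Path,
                       config_hash: str = "", seed: int | None = None,
                       stem: str = "map") -> dict[str, Path]:
    """Write t2star/r2star/rsq/mask NIfTI volumes, the PNG colourmap and
    a provenance file.  The PNG clips T2* to the fixed 0-60 ms scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, arr in (("t2star", r2map.t2star_ms), ("r2star", r2map.r2star),
                      ("rsq", r2map.r_squared),
                      ("mask", r2map.quality.astype(float))):
        p = outdir / f"{stem}_{name}.nii.gz"
        _save_scalar_nifti(arr, p)
        paths[name] = p

    fig, ax = plt.subplots(figsize=(5, 5))
    shown = np.where(r2map.quality, np.clip(r2map.t2star_ms, 0.0, T2STAR_DISPLAY_MAX_MS), 0.0)
    im = ax.imshow(shown, cmap="viridis", vmin=0.0, vmax=T2STAR_DISPLAY_MAX_MS)
    fig.colorbar(im, ax=ax, label="T2* (ms)")
    ax.set_title(f"T2* map ({r2map.method}), scale 0-{T2STAR_DISPLAY_MAX_MS:.0f} ms")
    ax.axis("off")
    png = outdir / f"{stem}_t2star.png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    paths["png"] = png

    prov = outdir / f"{stem}_provenance.txt"
    prov.write_text(
        f"tool_version: {__version__}\n"
        f"method: {r2map.method}\n"
        f"gate: {r2map.gate}\n"
        f"config_hash: {config_hash}\n"
        f"seed: {'' if seed is None else seed}\n"
    )
    paths["provenance"] = prov
    return paths


@dataclass
class StudyConfig:
    """Flat configuration for the end-to-end pipeline."""

    echo_times_ms: Sequence[float] = DEFAULT_ECHO_TIMES_MS
    field_strength: float = 1.5
    dose_mg_per_kg: float = DEFAULT_DOSE_MG_PER_KG  # metadata only
    gate_threshold: float = DEFAULT_R2_GATE
    min_echoes: int = DEFAULT_MIN_ECHOES
    fit_method: str = "loglinear"
    m_init: int = 3
    k_sigma: float = 3.0
    noise_sigma: float = 15.0
    n_subjects: int = 4
    image_size: tuple[int, int] = (96, 96)
    seed: int = 0
    output_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if te.size < 2 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times_ms must be strictly increasing, >= 2 entries")
        if not 0.0 < self.gate_threshold < 1.0:
            raise ValueError("gate_threshold must be in (0, 1)")
        if self.dose_mg_per_kg <= 0:
            raise ValueError("dose_mg_per_kg must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if float(self.field_strength) not in (1.5, 3.0):
            raise ValueError("field_strength must be 1.5 or 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "image_size" in raw:
            raw["image_size"] = tuple(raw["image_size"])
        if "echo_times_ms" in raw:
            raw["echo_times_ms"] = tuple(raw["echo_times_ms"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
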