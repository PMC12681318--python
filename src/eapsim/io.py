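"""File formats: EAP descriptors, phantoms, DWI stacks, run configuration.

All descriptor formats are plain text (JSON / CSV / FSL bvals-bvecs) so a
simulation is reproducible from its manifest alone; NIfTI output is offered
for interoperability with standard dMRI tooling.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np

from .eap import DiffusionTensorModel, MapMriEAP, ScEAP, ShCoefficients
from .gradients import GradientTable
from .phantom import PhantomSpec, VoxelSpec
from .sampling import DEFAULT_NU_VALUES
from .simulate import DwiStack, SequenceTiming


class ManifestError(IOError):
    """Raised when a stack directory and its manifest disagree or are missing."""


# ---------------------------------------------------------------------------
# EAP descriptor files
# ---------------------------------------------------------------------------

def eap_to_dict(eap, tau: float | None = None) -> dict:
    """Serializable descriptor for any supported EAP representation."""
    if isinstance(eap, DiffusionTensorModel):
        d = {"format": "tensor", "D": eap.D.tolist()}
        if tau is not None:
            d["tau"] = float(tau)
        return d
    if isinstance(eap, MapMriEAP):
        return {
            "format": "mapmri",
            "indices": eap.indices.tolist(),
            "coefficients": eap.coefficients.tolist(),
            "U": eap.U.tolist(),
            "scales": eap.scales.tolist(),
            "tau": float(eap.tau),
        }
    if isinstance(eap, ScEAP):
        return {
            "format": "sh_fodf",
            "L": int(eap.fodf.L),
            "coefficients": eap.fodf.values.tolist(),
            "lambda_par": float(eap.lambda_par),
            "lambda_perp": float(eap.lambda_perp),
            "tau": float(eap.tau),
        }
    raise TypeError(f"unsupported EAP type {type(eap).__name__}")


def eap_from_dict(d: dict):
    """Inverse of :func:`eap_to_dict`; returns ``(eap, tau_or_None)``."""
    fmt = d.get("format")
    if fmt == "tensor":
        return DiffusionTensorModel(np.asarray(d["D"], dtype=float)), d.get("tau")
    if fmt == "mapmri":
        eap = MapMriEAP(np.asarray(d["coefficients"], dtype=float),
                        np.asarray(d["indices"], dtype=int),
                        np.asarray(d["scales"], dtype=float),
                        np.asarray(d["U"], dtype=float), float(d["tau"]))
        return eap, eap.tau
    if fmt == "sh_fodf":
        fodf = ShCoefficients(np.asarray(d["coefficients"], dtype=float),
                              int(d["L"]))
        eap = ScEAP(fodf, float(d["lambda_par"]), float(d["lambda_perp"]),
                    float(d["tau"]))
        return eap, eap.tau
    raise ValueError(f"unknown EAP format {fmt!r}")


def write_eap(eap, path, tau: float | None = None) -> None:
    pathlib.Path(path).write_text(json.dumps(eap_to_dict(eap, tau), indent=1))


def read_eap(path):
    return eap_from_dict(json.loads(pathlib.Path(path).read_text()))


# ---------------------------------------------------------------------------
# Phantom files
# ---------------------------------------------------------------------------

def write_phantom(spec: PhantomSpec, path) -> None:
    doc = {
        "grid_shape": list(spec.grid_shape),
        "spacing": spec.spacing,
        "name": spec.name,
        "seed": spec.seed,
        "voxels": [
            {"index": list(v.index), "t1": v.t1, "t2": v.t2, "pd": v.pd,
             "eap": eap_to_dict(v.eap)}
            for v in spec.voxels
        ],
    }
    pathlib.Path(path).write_text(json.dumps(doc))


def read_phantom(path) -> PhantomSpec:
    doc = json.loads(pathlib.Path(path).read_text())
    voxels = tuple(
        VoxelSpec(tuple(v["index"]), eap_from_dict(v["eap"])[0],
                  v["t1"], v["t2"], v["pd"])
        for v in doc["voxels"]
    )
    return PhantomSpec(tuple(doc["grid_shape"]), doc["spacing"], voxels,
                       name=doc.get("name", ""), seed=doc.get("seed"))


# ---------------------------------------------------------------------------
# DWI stack containers
# ---------------------------------------------------------------------------

AXIS_ORDER = ("x", "y", "gradient")


def write_stack(stack: DwiStack, path, fmt: str = "text") -> None:
    """Write a stack directory with a JSON manifest.

    ``fmt='text'`` stores the complex signals losslessly as two float
    channels in CSV; ``fmt='nifti'`` writes real/imag NIfTI volumes of
    shape (nx, ny, 1, nvol).
    """
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nx, ny, nvol = stack.data.shape
    manifest = {
        "format": fmt,
        "axis_order": list(AXIS_ORDER),
        "grid_shape": [nx, ny],
        "n_volumes": nvol,
        "bvals": stack.bvals.tolist(),
        "bvecs": stack.bvecs.tolist(),
        "meta": stack.meta,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    mask_idx = np.argwhere(stack.mask)
    np.savetxt(path / "mask.csv", mask_idx, fmt="%d", delimiter=",",
               header="i,j", comments="")
    if fmt == "text":
        with open(path / "data.csv", "w") as fh:
            fh.write("i,j,volume,real,imag\n")
            for i, j in mask_idx:
                row = stack.data[i, j]
                for v in range(nvol):
                    fh.write(f"{i},{j},{v},{row[v].real:.17g},{row[v].imag:.17g}\n")
    elif fmt == "nifti":
        import nibabel as nib
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(stack.data.real.reshape(nx, ny, 1, nvol), affine),
                 str(path / "real.nii"))
        nib.save(nib.Nifti1Image(stack.data.imag.reshape(nx, ny, 1, nvol), affine),
                 str(path / "imag.nii"))
    else:
        raise ValueError(f"unknown stack format {fmt!r}")


def read_stack(path) -> DwiStack:
    path = pathlib.Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ManifestError(f"no manifest.json in {path}; refusing to guess a layout")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("axis_order") != list(AXIS_ORDER):
        raise ManifestError(f"unsupported axis order {manifest.get('axis_order')}")
    nx, ny = manifest["grid_shape"]
    nvol = manifest["n_volumes"]
    bvals = np.asarray(manifest["bvals"], dtype=float)
    bvecs = np.asarray(manifest["bvecs"], dtype=float)
    if bvals.size != nvol:
        raise ManifestError("manifest volume count disagrees with bvals")
    data = np.zeros((nx, ny, nvol), dtype=complex)
    mask = np.zeros((nx, ny), dtype=bool)
    fmt = manifest["format"]
    if fmt == "text":
        raw = np.genfromtxt(path / "data.csv", delimiter=",", names=True)
        raw = np.atleast_1d(raw)
        i = raw["i"].astype(int)
        j = raw["j"].astype(int)
        v = raw["volume"].astype(int)
        data[i, j, v] = raw["real"] + 1j * raw["imag"]
        mask[i, j] = True
    elif fmt == "nifti":
        import nibabel as nib
        real = np.asarray(nib.load(str(path / "real.nii")).dataobj)
        imag = np.asarray(nib.load(str(path / "imag.nii")).dataobj)
        if real.shape != (nx, ny, 1, nvol):
            raise ManifestError(
                f"NIfTI shape {real.shape} disagrees with manifest "
                f"{(nx, ny, 1, nvol)}")
        data = (real + 1j * imag).reshape(nx, ny, nvol)
        mask_idx = np.loadtxt(path / "mask.csv", delimiter=",", skiprows=1,
                              dtype=int, ndmin=2)
        mask[mask_idx[:, 0], mask_idx[:, 1]] = True
    else:
        raise ManifestError(f"unknown stack format {fmt!r}")
    return DwiStack(data, bvals, bvecs, mask, manifest.get("meta", {}))


# ---------------------------------------------------------------------------
# Run configuration and provenance
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Configuration serialized into every output manifest."""

    seed: int = 0
    spins_per_voxel: int = 2000
    nu_values: tuple = DEFAULT_NU_VALUES
    mapmri_grid_extent: float = 5.0
    mapmri_grid_step: float = 0.1
    sphere_grid: tuple = (180, 360)
    wrapper_safety: float = 1.05
    delta: float = 0.0166
    Delta: float = 0.0557
    TE: float = 0.113725
    TR: float = 50.033
    redraw_per_gradient: bool = True

    def timing(self) -> SequenceTiming:
        return SequenceTiming(self.delta, self.Delta, self.TE, self.TR)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nu_values"] = list(self.nu_values)
        d["sphere_grid"] = list(self.sphere_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "nu_values" in kwargs:
            kwargs["nu_values"] = tuple(kwargs["nu_values"])
        if "sphere_grid" in kwargs:
            kwargs["sphere_grid"] = tuple(kwargs["sphere_grid"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def provenance(config: RunConfig | None = None, extra: dict | None = None) -> dict:
    """Version and configuration fingerprint carried by output manifests."""
    import scipy

    from . import __version__
    cfg = (config or RunConfig()).to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    doc = {
        "eapsim_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "config": cfg,
        "config_hash": digest,
    }
    if extra:
        doc.update(extra)
    return doc
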