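"""Gradient tables in the FSL bvals/bvecs dialect.

``bvals`` is a single whitespace-separated row of b-values (s/mm^2);
``bvecs`` holds three rows (x, y, z) of unit direction columns, with zero
columns marking b = 0 baselines.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np


class GradientTableError(ValueError):
    """Raised for malformed bvals/bvecs files."""


@dataclasses.dataclass(frozen=True)
class GradientTable:
    bvals: np.ndarray  # (n,), s/mm^2
    bvecs: np.ndarray  # (n, 3), unit rows (zero rows allowed for b = 0)

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise GradientTableError(f"bvecs must be (n, 3), got {bvecs.shape}")
        if bvals.size != bvecs.shape[0]:
            raise GradientTableError(
                f"bvals ({bvals.size}) and bvecs ({bvecs.shape[0]}) lengths differ")
        if np.any(~np.isfinite(bvals)) or np.any(~np.isfinite(bvecs)):
            raise GradientTableError("NaN or infinite entries in the gradient table")
        if np.any(bvals < 0):
            raise GradientTableError("negative b-values")
        norms = np.linalg.norm(bvecs, axis=1)
        zero = norms < 1e-12
        if np.any(zero & (bvals > 1e-6)):
            bad = int(np.nonzero(zero & (bvals > 1e-6))[0][0])
            raise GradientTableError(f"zero direction with non-zero b at entry {bad}")
        bvecs = bvecs.copy()
        nonunit = ~zero & (np.abs(norms - 1.0) > 1e-12)
        if np.any(nonunit & (np.abs(norms - 1.0) > 1e-6)):
            n_bad = int(np.sum(nonunit & (np.abs(norms - 1.0) > 1e-6)))
            warnings.warn(
                f"{n_bad} gradient direction(s) were not unit vectors and "
                "have been normalized", stacklevel=2,
            )
        bvecs[nonunit] /= norms[nonunit, None]
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= 1e-6

    def __iter__(self):
        return iter(zip(self.bvals, self.bvecs))


def _parse_rows(path, expected_rows: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise GradientTableError(f"{path}:{lineno}: {exc}") from None
    if len(rows) != expected_rows:
        raise GradientTableError(
            f"{path}: expected {expected_rows} row(s), found {len(rows)}")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise GradientTableError(f"{path}: ragged rows with lengths {sorted(ncols)}")
    return np.asarray(rows, dtype=float)


def read_gradient_table(bvals_path, bvecs_path) -> GradientTable:
    """Read an FSL-style (bvals, bvecs) pair."""
    bvals = _parse_rows(bvals_path, 1)[0]
    bvecs = _parse_rows(bvecs_path, 3)
    if bvecs.shape[1] != bvals.size:
        raise GradientTableError(
            f"bvals has {bvals.size} entries but bvecs has {bvecs.shape[1]} columns")
    return GradientTable(bvals, bvecs.T)


def write_gradient_table(table: GradientTable, bvals_path, bvecs_path) -> None:
    """Write the FSL dialect (bvals one row, bvecs three rows)."""
    with open(bvals_path, "w") as fh:
        fh.write(" ".join(f"{b:.17g}" for b in table.bvals) + "\n")
    with open(bvecs_path, "w") as fh:
        for ax in range(3):
            fh.write(" ".join(f"{v:.17g}" for v in table.bvecs[:, ax]) + "\n")
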