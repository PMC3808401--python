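"""TPS landmark I/O and Generalized Procrustes Analysis.

Each specimen carries 17 (x, y) landmarks outlining the lateral body
profile. GPA removes the non-shape variation — translation, scale and
rotation — by centering every configuration, rescaling it to unit centroid
size, and iteratively rotating all configurations onto their evolving mean
shape (rotation only, no reflection, the standard geometric-morphometrics
convention). The superimposed coordinates (34 per specimen) are the shape
variables appended to the image features for classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LabelMismatchError, TPSFormatError
from .select import LabeledFeatureTable

N_LANDMARKS = 17


@dataclass
class LandmarkSet:
    """17 ordered (x, y) landmark coordinates for one specimen."""

    coords: np.ndarray
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected {N_LANDMARKS} (x, y) landmarks, "
                             f"got shape {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite landmark coordinates")
        uniq = np.unique(self.coords, axis=0)
        if len(uniq) < N_LANDMARKS:
            warnings.warn(f"{self.specimen_id or 'specimen'}: coincident landmarks",
                          stacklevel=2)

    def centroid_size(self) -> float:
        centered = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((centered ** 2).sum()))


def read_tps(path: str | Path, flip_y: float | None = None) -> list[LandmarkSet]:
    """Read a TPS landmark file (LM= / coordinate lines / ID= / IMAGE=).

    Coordinates are taken verbatim (the TPS convention is Cartesian,
    y increasing upward). For files digitised in raster coordinates pass
    ``flip_y`` = image height to convert y -> height - y.
    """
    path = Path(path)
    sets: list[LandmarkSet] = []
    lm_expected = 0
    coords: list[list[float]] = []
    spec_id = ""
    record_no = 0

    def flush(line_no: int) -> None:
        nonlocal coords, spec_id, lm_expected
        if lm_expected == 0:
            return
        if len(coords) != lm_expected:
            raise TPSFormatError(
                f"{path.name} record {record_no}: {len(coords)} coordinate "
                f"lines for LM={lm_expected} (near line {line_no})")
        arr = np.asarray(coords, dtype=float)
        if flip_y is not None:
            arr[:, 1] = flip_y - arr[:, 1]
        sets.append(LandmarkSet(coords=arr,
                                specimen_id=spec_id or f"specimen_{len(sets)}"))
        coords, spec_id, lm_expected = [], "", 0

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(line_no)
                record_no += 1
                try:
                    lm_expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSFormatError(f"{path.name} line {line_no}: "
                                         f"bad LM header {line!r}") from exc
                if lm_expected != N_LANDMARKS:
                    raise TPSFormatError(
                        f"{path.name} record {record_no}: expected "
                        f"{N_LANDMARKS} landmarks, got LM={lm_expected}")
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise TPSFormatError(f"{path.name} line {line_no}: "
                                         f"malformed coordinate line {line!r}")
                try:
                    coords.append([float(parts[0]), float(parts[1])])
                except ValueError as exc:
                    raise TPSFormatError(f"{path.name} line {line_no}: "
                                         f"non-numeric coordinates") from exc
    flush(line_no=-1)
    if not sets:
        raise TPSFormatError(f"{path.name}: no landmark records")
    return sets


def write_tps(sets: list[LandmarkSet], path: str | Path) -> None:
    """Write landmark sets in the TPS dialect read by :func:`read_tps`."""
    with open(Path(path), "w") as fh:
        for s in sets:
            fh.write(f"LM={N_LANDMARKS}\n")
            for x, y in s.coords:
                fh.write(f"{x:.6f} {y:.6f}\n")
            if s.specimen_id:
                fh.write(f"ID={s.specimen_id}\n")


@dataclass
class ProcrustesResult:
    """Superimposed configurations and the consensus (mean) shape."""

    aligned: np.ndarray          # (n, 17, 2)
    consensus: np.ndarray        # (17, 2)
    centroid_sizes: np.ndarray   # (n,) original sizes
    specimen_ids: list[str]
    iterations: int
    converged: bool


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    size = np.sqrt((centered ** 2).sum())
    if size == 0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return centered / size, float(size)


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation (no reflection) aligning source onto target."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def gpa(configs: list[LandmarkSet], tol: float = 1e-10,
        max_iter: int = 100) -> ProcrustesResult:
    """Generalized Procrustes superimposition of >= 2 configurations.

    Iteration: center each configuration and scale it to unit centroid
    size; rotate every configuration onto the current consensus; replace
    the consensus by the mean of the rotated configurations (re-centered,
    re-scaled to unit size); stop when the consensus moves less than
    ``tol`` in Frobenius norm.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    shapes = np.empty((len(configs), N_LANDMARKS, 2))
    sizes = np.empty(len(configs))
    for i, c in enumerate(configs):
        shapes[i], sizes[i] = _center_and_scale(c.coords)

    consensus = shapes[0].copy()
    converged = False
    for iteration in range(1, max_iter + 1):
        rotated = np.stack([s @ _optimal_rotation(s, consensus) for s in shapes])
        new_consensus = rotated.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        norm = np.sqrt((new_consensus ** 2).sum())
        if norm == 0:
            raise ValueError("degenerate consensus shape")
        new_consensus /= norm
        change = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        shapes = rotated
        if change < tol:
            converged = True
            break
    return ProcrustesResult(
        aligned=shapes, consensus=shapes.mean(axis=0), centroid_sizes=sizes,
        specimen_ids=[c.specimen_id for c in configs],
        iterations=iteration, converged=converged)


def procrustes_coordinate_names() -> list[str]:
    """Column names ProcCoord_1x, ProcCoord_1y, ..., ProcCoord_17y."""
    names = []
    for lm in range(1, N_LANDMARKS + 1):
        names.extend([f"ProcCoord_{lm}x", f"ProcCoord_{lm}y"])
    return names


def procrustes_coordinates(result: ProcrustesResult) -> pd.DataFrame:
    """Flatten aligned configurations to an n x 34 shape-variable table."""
    if not result.converged:
        warnings.warn("GPA did not converge; coordinates may be unstable",
                      stacklevel=2)
    flat = result.aligned.reshape(len(result.aligned), 2 * N_LANDMARKS)
    return pd.DataFrame(flat, index=result.specimen_ids,
                        columns=procrustes_coordinate_names())


def combine(features: LabeledFeatureTable,
            shapes: pd.DataFrame) -> LabeledFeatureTable:
    """Append the shape variables to the image-feature table (48 + 34 = 82).

    Specimen ids must match in the same order; an empty shape table is
    passed through with a warning.
    """
    if shapes.shape[1] == 0 or len(shapes) == 0:
        warnings.warn("empty shape matrix; returning features unchanged",
                      stacklevel=2)
        return features
    if list(features.X.index) != list(shapes.index):
        offenders = [i for i, (a, b) in
                     enumerate(zip(features.X.index, shapes.index)) if a != b]
        raise LabelMismatchError(
            f"specimen id mismatch between features and shapes at rows "
            f"{offenders[:10]}")
    X = pd.concat([features.X, shapes], axis=1)
    return LabeledFeatureTable(X, features.y.copy())
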