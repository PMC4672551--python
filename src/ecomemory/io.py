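"""Serialization: configs, matrices, states, patterns, logs, manifests.

All on-disk formats are plain text except the optional PGM (P5) pattern
images, which follow the pictogram convention: a black pixel marks a
species with elevated carrying capacity (+1), a white pixel a depressed
one (-1), and the pixel at column ``x``, row ``y`` of a ``width`` x
``height`` image maps to the ``(width*y + x)``-th species (row-major).
Matrix and state files store floats at full precision so round trips are
bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import yaml

from .dynamics import CommunityMatrix, EcosystemState
from .environments import EnvironmentPattern
from .experiments import CensusRow, EvoConfig, Trajectory

__all__ = [
    "load_config",
    "save_config",
    "write_matrix",
    "read_matrix",
    "write_state",
    "read_state",
    "export_pattern_image",
    "import_pattern_image",
    "write_pattern_grid",
    "read_pattern_grid",
    "write_trajectory_log",
    "write_trajectory_summary",
    "write_census_table",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"

_CONFIG_FIELDS = {f.name for f in dataclasses.fields(EvoConfig)}


def load_config(path: Union[str, Path]) -> EvoConfig:
    """Read an EvoConfig from JSON or YAML; omitted keys take the defaults,
    unknown keys are rejected by name."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config document must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    if "env_sequence" in data:
        data["env_sequence"] = tuple(data["env_sequence"])
    return EvoConfig(**data)


def save_config(config: EvoConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


# ---------------------------------------------------------------------------
# matrices and states

def write_matrix(matrix: CommunityMatrix, path: Union[str, Path]) -> None:
    """Square delimited-text matrix, row-major, full precision; the
    conserved budget vector Q is stored in a header comment."""
    path = Path(path)
    q_line = "# Q " + " ".join(_FLOAT_FMT % q for q in matrix.Q)
    header = f"# community matrix N={matrix.n_species}\n{q_line}\n"
    body = "\n".join(
        "\t".join(_FLOAT_FMT % v for v in row) for row in matrix.omega
    )
    path.write_text(header + body + "\n")


def read_matrix(path: Union[str, Path]) -> CommunityMatrix:
    path = Path(path)
    q: Optional[np.ndarray] = None
    rows: List[List[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("# Q "):
                q = np.array([float(v) for v in line[4:].split()])
            continue
        try:
            rows.append([float(v) for v in line.split()])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed matrix row") from exc
    if not rows:
        raise ValueError(f"{path}: no matrix rows found")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged rows in matrix file")
    omega = np.array(rows, dtype=float)
    if omega.shape[0] != omega.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({omega.shape})")
    return CommunityMatrix(omega, q)


def write_state(state: EcosystemState, path: Union[str, Path]) -> None:
    """One density per line, full precision."""
    Path(path).write_text(
        "\n".join(_FLOAT_FMT % v for v in state.densities) + "\n"
    )


def read_state(path: Union[str, Path], time: int = 0) -> EcosystemState:
    values = [
        float(line)
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return EcosystemState(np.array(values), time)


# ---------------------------------------------------------------------------
# pattern images (PGM P5: black = +1 = elevated capacity) and text grids

def export_pattern_image(
    pattern: EnvironmentPattern, width: int, height: int, path: Union[str, Path]
) -> None:
    if width * height != pattern.n_species:
        raise ValueError(
            f"width*height = {width * height} does not match N = {pattern.n_species}"
        )
    pixels = np.where(pattern.xi > 0, 0, 255).astype(np.uint8)  # black = +1
    header = f"P5\n{width} {height}\n255\n".encode("ascii")
    Path(path).write_bytes(header + pixels.tobytes())


def import_pattern_image(path: Union[str, Path], label: str = "") -> EnvironmentPattern:
    raw = Path(path).read_bytes()
    tokens: List[bytes] = []
    idx = 0
    while len(tokens) < 4:
        # skip whitespace and comment lines in the header
        while idx < len(raw) and raw[idx : idx + 1].isspace():
            idx += 1
        if raw[idx : idx + 1] == b"#":
            while idx < len(raw) and raw[idx : idx + 1] != b"\n":
                idx += 1
            continue
        start = idx
        while idx < len(raw) and not raw[idx : idx + 1].isspace():
            idx += 1
        tokens.append(raw[start:idx])
    if tokens[0] != b"P5":
        raise ValueError(f"{path}: not a binary PGM (P5) file")
    width, height, maxval = (int(t) for t in tokens[1:4])
    idx += 1  # single whitespace after maxval
    pixels = np.frombuffer(raw[idx : idx + width * height], dtype=np.uint8)
    if pixels.size != width * height:
        raise ValueError(f"{path}: truncated PGM pixel data")
    values = set(np.unique(pixels).tolist())
    if not values <= {0, maxval}:
        raise ValueError(
            f"{path}: non-binary image values {sorted(values)}; expected 0/{maxval}"
        )
    xi = np.where(pixels == 0, 1.0, -1.0)
    return EnvironmentPattern(xi, label=label)


def write_pattern_grid(
    pattern: EnvironmentPattern, width: int, height: int, path: Union[str, Path]
) -> None:
    """Plain text {-1,+1} grid, row-major, with a 'width height' comment header."""
    if width * height != pattern.n_species:
        raise ValueError(
            f"width*height = {width * height} does not match N = {pattern.n_species}"
        )
    grid = pattern.xi.astype(int).reshape(height, width)
    lines = [f"# {width} {height}"]
    lines += [" ".join(f"{v:+d}" for v in row) for row in grid]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pattern_grid(path: Union[str, Path], label: str = "") -> EnvironmentPattern:
    """Read a row-major text grid of {0,1} or {-1,+1} (1 = elevated = +1)."""
    values: List[float] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        values.extend(float(v) for v in line.split())
    arr = np.array(values)
    uniq = set(np.unique(arr).tolist())
    if uniq <= {0.0, 1.0}:
        arr = 2.0 * arr - 1.0
    elif not uniq <= {-1.0, 1.0}:
        raise ValueError(f"{path}: grid values must be {{0,1}} or {{-1,+1}}")
    return EnvironmentPattern(arr, label=label)


# ---------------------------------------------------------------------------
# run outputs

def write_trajectory_log(trajectory: Trajectory, path: Union[str, Path]) -> None:
    """Per-generation JSON-lines log: environment, overlap with each
    pattern, relaxation length and conservation residuals."""
    with Path(path).open("w") as fh:
        for rec in trajectory.records:
            fh.write(
                json.dumps(
                    {
                        "generation": rec.generation,
                        "environment": rec.env_label,
                        "n_steps": rec.n_steps,
                        "converged": rec.converged,
                        "overlaps": rec.overlaps,
                        "max_row_residual": rec.max_row_residual,
                        "max_col_residual": rec.max_col_residual,
                        "max_asymmetry": rec.max_asymmetry,
                        "mean_density": float(rec.densities.mean()),
                        "min_density": float(rec.densities.min()),
                        "max_density": float(rec.densities.max()),
                    }
                )
                + "\n"
            )


def write_trajectory_summary(trajectory: Trajectory, path: Union[str, Path]) -> None:
    """Tab-delimited per-generation summary: generation, environment, mean,
    min and max density plus the overlap with each pattern."""
    labels = [p.label for p in trajectory.patterns]
    header = "generation\tenvironment\tmean\tmin\tmax\t" + "\t".join(
        f"overlap_{lbl}" for lbl in labels
    )
    lines = [header]
    for rec in trajectory.records:
        x = rec.densities
        lines.append(
            "\t".join(
                [str(rec.generation), rec.env_label,
                 f"{x.mean():.8g}", f"{x.min():.8g}", f"{x.max():.8g}"]
                + [f"{rec.overlaps[lbl]:+.4f}" for lbl in labels]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_census_table(rows: Sequence[CensusRow], path: Union[str, Path]) -> None:
    """Tab-delimited census: generation, attractor count, basin counts and
    per-attractor overlaps."""
    lines = ["generation\tn_attractors\tbasin_counts\toverlaps\tdistances"]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    str(row.generation),
                    str(row.n_attractors),
                    ",".join(str(c) for c in row.basin_counts),
                    ";".join(
                        ",".join(f"{o:.4f}" for o in ovl) for ovl in row.overlaps
                    ),
                    ",".join(f"{d:.6g}" for d in row.distances),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(
    config: EvoConfig, path: Union[str, Path], extra: Optional[dict] = None
) -> None:
    """Everything needed to reproduce a run bit-exactly: full config
    (including both seed streams) and the package version."""
    from . import __version__

    manifest = {"package": "ecomemory", "version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
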