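"""Plain-text persistence for skeleton sequences and dataset manifests.

One session is a CSV with a ``t`` column plus 60 coordinate columns named
``<joint>_<axis>`` in canonical joint order, and a JSON metadata sidecar
(``<name>.meta.json``) carrying subject/session/gender/fps. A dataset is a
``manifest.csv`` with columns ``subject_id, session_id, gender, path``.

CSV was chosen over a binary container so fixtures and generated cohorts
stay inspectable with standard tools; coordinates are serialized with 12
significant digits so a round trip is exact to well below 1e-9 m.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .skeleton import COORD_NAMES, N_JOINTS, SkeletonError, SkeletonSequence

__all__ = ["write_sequence", "read_sequence", "load_dataset", "write_manifest",
           "ParseError"]

HEADER = ("t",) + COORD_NAMES


class ParseError(ValueError):
    """Malformed skeleton file or manifest."""


def write_sequence(seq: SkeletonSequence, path: str | Path) -> Path:
    """Write ``seq`` to ``path`` as CSV plus a ``.meta.json`` sidecar."""
    seq.validate()
    path = Path(path)
    data = np.column_stack([seq.timestamps, seq.to_frame_vectors()])
    df = pd.DataFrame(data, columns=list(HEADER))
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "subject_id": seq.subject_id,
        "session_id": seq.session_id,
        "gender": seq.gender,
        "fps": seq.fps,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    return path


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(path.suffix + ".meta.json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


def read_sequence(path: str | Path) -> SkeletonSequence:
    """Read and validate one session CSV.

    Raises :class:`ParseError` for an empty file, a header that deviates
    from the canonical joint/axis order, a wrong column count, or
    non-increasing timestamps.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if tuple(df.columns) != HEADER:
        raise ParseError(
            f"{path}: header mismatch at line 1 — expected canonical "
            f"'t,<joint>_<axis>' order with {len(HEADER)} columns, "
            f"got {len(df.columns)} columns"
        )
    if len(df) == 0:
        raise ParseError(f"{path}: no frames after header (line 2)")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0, 0]) + 2
        raise ParseError(f"{path}: non-numeric value at line {bad}")
    t = values[:, 0]
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 3
        raise ParseError(f"{path}: non-increasing timestamp at line {bad}")
    meta = _sidecar(path)
    try:
        return SkeletonSequence(
            timestamps=t,
            positions=values[:, 1:].reshape(len(t), N_JOINTS, 3),
            subject_id=str(meta.get("subject_id", "")),
            session_id=str(meta.get("session_id", "")),
            gender=str(meta.get("gender", "")),
            fps=float(meta.get("fps", 24.0)),
        )
    except SkeletonError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    """Write a dataset manifest (subject_id, session_id, gender, path)."""
    path = Path(path)
    pd.DataFrame(rows, columns=["subject_id", "session_id", "gender", "path"]).to_csv(
        path, index=False
    )
    return path


def load_dataset(manifest_path: str | Path):
    """Load every session listed in a manifest.

    Returns a list of ``(SkeletonSequence, gender, subject_id)`` tuples in
    manifest order; sessions are never merged, so subject-wise grouping for
    cross-validation is preserved downstream. Paths are resolved relative
    to the manifest's directory. A missing file raises :class:`ParseError`
    naming the offending manifest row.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "session_id", "gender", "path"}
    if not required.issubset(df.columns):
        raise ParseError(f"{manifest_path}: manifest missing columns {required - set(df.columns)}")
    out = []
    for i, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.exists():
            raise ParseError(
                f"{manifest_path}: row {i + 2} references missing file {row['path']}"
            )
        seq = read_sequence(p)
        out.append((seq, str(row["gender"]), str(row["subject_id"])))
    return out


def write_cohort(cohort, out_dir: str | Path, seed: int = 0,
                 generate=None) -> Path:
    """Materialize a sampled cohort to disk: one CSV per session + manifest.

    ``generate`` defaults to :func:`gaitlab.synthetic_gait.generate_walk`;
    session seeds are derived deterministically from ``seed``.
    """
    from .synthetic_gait import generate_walk as _gen

    generate = generate or _gen
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, subj in enumerate(cohort.subjects):
        for k in range(cohort.sessions_per_subject):
            child = np.random.SeedSequence(entropy=int(seed), spawn_key=(i, k))
            sess_seed = int(child.generate_state(1)[0] % (2**31))
            seq = generate(
                subj,
                cohort.session_duration,
                cohort.fps,
                seed=sess_seed,
                session_id=f"sess{k:02d}",
            )
            fname = f"{subj.subject_id}_sess{k:02d}.csv"
            write_sequence(seq, out_dir / fname)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "session_id": f"sess{k:02d}",
                    "gender": subj.gender,
                    "path": fname,
                }
            )
    return write_manifest(rows, out_dir / "manifest.csv")
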