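"""File-format glue: silhouette directories, manifests, configs, exports.

Directory convention for a cohort on disk: one subdirectory per subject,
frames as 8-bit grayscale PNG or PGM in lexicographic order, plus a
``manifest.csv`` with columns ``subject_id,label[,order_index]`` at the
top level. Any nonzero pixel is treated as foreground (255) on ingest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import EmptyInputError
from .types import FGEI, GEI, DetectionRecord, FeatureVector, GaitSequence, RawFrame

logger = logging.getLogger(__name__)

__all__ = [
    "read_frame",
    "read_sequence_dir",
    "read_cohort_dir",
    "write_sequence_dir",
    "write_cohort",
    "write_energy_png",
    "save_fgei",
    "load_fgei",
    "features_to_csv",
    "records_to_frame",
    "write_report",
    "load_config",
]

FRAME_SUFFIXES = (".png", ".pgm")


def read_frame(path: Path | str) -> np.ndarray:
    """Load one frame as {0, 255} uint8; nonzero gray levels are coerced
    to foreground (logged once per file when coercion happens)."""
    arr = np.asarray(Image.open(path).convert("L"))
    nonbinary = np.count_nonzero((arr != 0) & (arr != 255))
    if nonbinary:
        logger.info("%s: coerced %d non-binary pixels to foreground", path, nonbinary)
    return np.where(arr > 0, np.uint8(255), np.uint8(0))


def read_sequence_dir(
    path: Path | str, *, subject_id: str | None = None, true_label: str | None = None
) -> GaitSequence:
    """Read one subject's frames (lexicographic order) from a directory."""
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in FRAME_SUFFIXES)
    if not files:
        raise EmptyInputError(f"no PNG/PGM frames under {path}")
    frames = [read_frame(p) for p in files]
    return GaitSequence(
        subject_id=subject_id or path.name, frames=frames, true_label=true_label
    )


def read_cohort_dir(path: Path | str) -> tuple[list[GaitSequence], pd.DataFrame]:
    """Read a full cohort directory; subject order follows the manifest's
    ``order_index`` when present, else the manifest row order."""
    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv")
    if "order_index" in manifest.columns:
        manifest = manifest.sort_values("order_index").reset_index(drop=True)
    label_col = manifest["label"] if "label" in manifest.columns else [None] * len(manifest)
    sequences = [
        read_sequence_dir(path / str(sid), subject_id=str(sid), true_label=lab)
        for sid, lab in zip(manifest["subject_id"], label_col)
    ]
    return sequences, manifest


def write_sequence_dir(sequence: GaitSequence, path: Path | str) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for j, frame in enumerate(sequence.frames):
        Image.fromarray(frame).save(path / f"frame_{j:03d}.png")


def write_cohort(
    sequences: list[GaitSequence],
    manifest: pd.DataFrame,
    path: Path | str,
    spec_echo: dict | None = None,
) -> None:
    """Write a cohort in the directory layout the reader expects, plus the
    generating parameters echoed as YAML for provenance."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for seq in sequences:
        write_sequence_dir(seq, path / seq.subject_id)
    manifest.to_csv(path / "manifest.csv", index=False)
    if spec_echo is not None:
        (path / "cohort.yaml").write_text(yaml.safe_dump(spec_echo, sort_keys=False))


def write_energy_png(image: GEI | FGEI, path: Path | str) -> None:
    """8-bit rounded export for visual inspection (lossy; see save_fgei)."""
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def save_fgei(fgei: FGEI, path: Path | str) -> None:
    """Lossless pipeline state: float grid + accumulation counter."""
    np.savez(path, pixels=fgei.pixels, m_count=np.int64(fgei.m_count))


def load_fgei(path: Path | str) -> FGEI:
    data = np.load(path)
    return FGEI(pixels=data["pixels"], m_count=int(data["m_count"]))


def features_to_csv(
    vectors: list[FeatureVector],
    path: Path | str,
    overlaps: dict[str, np.ndarray] | None = None,
) -> None:
    """subject_id, mean, std — plus the full per-frame overlap row when given."""
    rows = []
    for v in vectors:
        row = {"subject_id": v.subject_id, "mean": v.mean, "std": v.std}
        if overlaps and v.subject_id in overlaps:
            row.update({f"o_{j + 1}": x for j, x in enumerate(overlaps[v.subject_id])})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def records_to_frame(records: list[DetectionRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def write_report(report_dict: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2) + "\n")


def load_config(path: Path | str) -> dict:
    """Read a YAML (or TOML) run config into a plain dict."""
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        import tomllib

        return tomllib.loads(path.read_text())
    return yaml.safe_load(path.read_text()) or {}
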