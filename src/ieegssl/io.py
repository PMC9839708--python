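"""Manifests, array containers, artifacts, and run configuration.

Formats are deliberately minimal and language-portable: CSV manifests and
predictions, NPZ array containers keyed by segment_id, JSON metric reports,
and NPZ artifacts whose JSON header records the config and code version.
"""

from __future__ import annotations

import hashlib
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoencoder import AEConfig, TemporalAutoencoder
from .kde import ClassKDE, KDEClassifier
from .synthetic import CLASS_NAMES, UNLABELED, SegmentRecord

__all__ = [
    "Manifest", "ManifestError", "ArtifactError", "read_manifest", "write_manifest",
    "save_segments", "load_segments", "save_embeddings", "load_embeddings",
    "save_model", "load_model", "save_classifier", "load_classifier",
    "load_run_config", "config_hash",
]

MANIFEST_COLUMNS = ["segment_id", "patient_id", "institution", "label",
                    "sampling_rate_hz", "array_key"]
_VALID_LABELS = set(CLASS_NAMES) | {UNLABELED}
_ARTIFACT_VERSION = 1


class ManifestError(ValueError):
    pass


class ArtifactError(ValueError):
    pass


@dataclass
class Manifest:
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rows
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns {missing}")
        dup = df["segment_id"][df["segment_id"].duplicated()]
        if len(dup):
            raise ManifestError(f"duplicate segment_id(s): {sorted(set(dup))}")
        bad = df.index[~df["label"].astype(int).isin(_VALID_LABELS)]
        if len(bad):
            rows = ", ".join(f"line {i + 2}" for i in bad[:5])  # +2: header + 1-basing
            raise ManifestError(
                f"label(s) outside {sorted(_VALID_LABELS)} at {rows}"
            )
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, Manifest) and self.rows.equals(other.rows)

    @classmethod
    def from_segments(cls, segments: list[SegmentRecord]) -> "Manifest":
        return cls(pd.DataFrame([
            {"segment_id": s.segment_id, "patient_id": s.patient_id,
             "institution": s.institution, "label": s.label,
             "sampling_rate_hz": s.sampling_rate_hz, "array_key": s.segment_id}
            for s in segments
        ]))


def read_manifest(path: str | Path) -> Manifest:
    try:
        df = pd.read_csv(path, dtype={"segment_id": str, "patient_id": str,
                                      "institution": str, "array_key": str})
    except Exception as exc:
        raise ManifestError(f"cannot read manifest {path!r}: {exc}") from exc
    if df.empty and set(MANIFEST_COLUMNS) <= set(df.columns):
        df = df.astype({"label": int}, errors="ignore")
    return Manifest(df)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.rows.to_csv(path, index=False)


# ----------------------------------------------------------- array containers

def save_segments(segments: list[SegmentRecord], array_path: str | Path,
                  manifest_path: str | Path | None = None) -> Manifest:
    """Write sample vectors to one NPZ keyed by segment_id (+ optional manifest CSV)."""
    np.savez_compressed(array_path, **{s.segment_id: s.samples for s in segments})
    manifest = Manifest.from_segments(segments)
    if manifest_path is not None:
        write_manifest(manifest, manifest_path)
    return manifest


def load_segments(manifest: Manifest | str | Path, array_path: str | Path) -> list[SegmentRecord]:
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    with np.load(array_path) as arrays:
        return [
            SegmentRecord(
                segment_id=row.segment_id, samples=arrays[row.array_key],
                sampling_rate_hz=float(row.sampling_rate_hz), label=int(row.label),
                patient_id=row.patient_id, institution=row.institution,
            )
            for row in manifest.rows.itertuples()
        ]


def save_embeddings(ids: list[str], embeddings: np.ndarray, path: str | Path) -> None:
    np.savez_compressed(path, **{i: e for i, e in zip(ids, embeddings)})


def load_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    with np.load(path) as arrays:
        ids = list(arrays.files)
        return ids, np.stack([arrays[i] for i in ids])


# ------------------------------------------------------------------ artifacts

def _save_artifact(path: str | Path, kind: str, header: dict,
                   arrays: dict[str, np.ndarray]) -> None:
    header = {"artifact_version": _ARTIFACT_VERSION, "kind": kind,
              "code_version": __version__, **header}
    np.savez_compressed(path, __header__=np.array(json.dumps(header)), **arrays)


def _load_artifact(path: str | Path, kind: str) -> tuple[dict, dict[str, np.ndarray]]:
    try:
        with np.load(path, allow_pickle=False) as data:
            header = json.loads(str(data["__header__"]))
            arrays = {k: data[k] for k in data.files if k != "__header__"}
    except (zipfile.BadZipFile, OSError, KeyError, json.JSONDecodeError) as exc:
        raise ArtifactError(f"corrupt or unreadable artifact {path!r}: {exc}") from exc
    if header.get("artifact_version") != _ARTIFACT_VERSION:
        raise ArtifactError(f"artifact version {header.get('artifact_version')} "
                            f"!= supported {_ARTIFACT_VERSION}")
    if header.get("kind") != kind:
        raise ArtifactError(f"artifact kind {header.get('kind')!r}, expected {kind!r}")
    return header, arrays


def save_model(model: TemporalAutoencoder, path: str | Path,
               history: dict | None = None) -> None:
    header = {"config": asdict(model.config), "frame_dim": model.frame_dim,
              "history": history or {}}
    _save_artifact(path, "autoencoder", header, model.get_weights())


def load_model(path: str | Path) -> TemporalAutoencoder:
    header, arrays = _load_artifact(path, "autoencoder")
    model = TemporalAutoencoder(header["frame_dim"], AEConfig(**header["config"]))
    model.set_weights(arrays)
    return model


def save_classifier(clf: KDEClassifier, path: str | Path) -> None:
    header = {"classes": clf.classes, "priors": list(map(float, clf.priors))}
    arrays = {}
    for c, kde in clf.kdes.items():
        arrays[f"points_{c}"] = kde.points
        arrays[f"bandwidths_{c}"] = kde.bandwidths
    _save_artifact(path, "kde_classifier", header, arrays)


def load_classifier(path: str | Path) -> KDEClassifier:
    header, arrays = _load_artifact(path, "kde_classifier")
    kdes = {c: ClassKDE(c, arrays[f"points_{c}"], arrays[f"bandwidths_{c}"])
            for c in header["classes"]}
    return KDEClassifier(kdes=kdes, priors=np.array(header["priors"]))


# ---------------------------------------------------------------- run config

_KNOWN_SECTIONS = {"seed", "out_dir", "generator", "spectro", "ae", "protocol", "projection"}


def load_run_config(path: str | Path) -> dict:
    """YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ManifestError("run config must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ManifestError(f"unknown config key(s): {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
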