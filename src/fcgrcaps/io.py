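"""File formats and checkpoints: FASTA in, TSV/JSON/npz out.

All writers are atomic (write to a temp file in the target directory, then
rename), so an interrupted run never leaves a half-written checkpoint or
table behind.  Model checkpoints are versioned ``.npz`` containers holding
the architecture config, the learned arrays, the class labels and the
training seed, and round-trip bit-exactly.
"""

from __future__ import annotations

import json
import os
import tempfile
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .capsnet import CapsNetConfig
from .estimators import CapsNetClassifier, DenseHeadClassifier
from .fcgr import FCGRImage, SequenceRecord, normalize_residues

__all__ = [
    "FormatError",
    "IntegrityError",
    "read_fasta",
    "write_fasta",
    "load_labels",
    "write_labels",
    "save_model",
    "load_model",
    "write_fcgr_text",
    "save_fcgr_stack",
    "load_fcgr_stack",
    "export_fcgr_png",
    "write_tsv",
    "write_json",
]

CHECKPOINT_SCHEMA_VERSION = 1
ALLOWED_LABELS = ("enhancer", "nonenhancer", "strong", "weak")


class FormatError(ValueError):
    """Malformed input file."""


class IntegrityError(ValueError):
    """Corrupt or truncated checkpoint."""


def _atomic_write(path, write_fn, mode="w"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, mode) as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_fasta(path, policy: str = "strict") -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA into normalized
    SequenceRecords, preserving order.

    A ``|label=...`` token in the header is accepted as an inline label
    fallback (labels normally live in a sidecar TSV).  Raises
    :class:`FormatError` on an empty file or a file whose first
    non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}:{lineno}: expected FASTA header, got {line[:30]!r}")
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = None
        for token in rec.description.split("|"):
            if token.strip().startswith("label="):
                label = token.strip()[len("label="):]
        residues = normalize_residues(str(rec.seq), policy, record_id=rec.id)
        records.append(SequenceRecord(rec.id, residues, label))
    return records


def write_fasta(records, path) -> None:
    def _w(fh):
        for r in records:
            header = f">{r.id}" + (f" |label={r.label}" if r.label else "")
            fh.write(header + "\n")
            for i in range(0, len(r.residues), 70):
                fh.write(r.residues[i:i + 70] + "\n")
    _atomic_write(path, _w)


def load_labels(path, fasta_ids=None) -> dict[str, str]:
    """Two-column TSV (id, label) -> id->label map.

    Rejects duplicate ids and unknown label tokens; when ``fasta_ids`` is
    given, every labeled id must exist in it.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}")
            rid, label = parts[0].strip(), parts[1].strip().lower()
            if rid in labels:
                raise FormatError(f"{path}:{lineno}: duplicate id {rid!r}")
            if label not in ALLOWED_LABELS:
                raise FormatError(f"{path}:{lineno}: unknown label {label!r}; "
                                  f"allowed: {', '.join(ALLOWED_LABELS)}")
            labels[rid] = label
    if fasta_ids is not None:
        unknown = set(labels) - set(fasta_ids)
        if unknown:
            raise FormatError(f"{path}: labeled ids missing from FASTA: "
                              f"{sorted(unknown)[:5]}")
    return labels


def write_labels(labels: dict[str, str], path) -> None:
    _atomic_write(path, lambda fh: fh.writelines(f"{k}\t{v}\n" for k, v in labels.items()))


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

_KIND_TO_CLS = {"capsnet": CapsNetClassifier, "densehead": DenseHeadClassifier}


def save_model(clf, path) -> None:
    """Serialize a fitted classifier to a versioned single-file container."""
    if not hasattr(clf, "net_"):
        raise ValueError("model must be fitted before saving")
    kind = "densehead" if isinstance(clf, DenseHeadClassifier) else "capsnet"
    from dataclasses import asdict
    meta = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "kind": kind,
        "config": asdict(clf.config_),
        "classes": [str(c) for c in clf.classes_],
        "n_epochs": clf.n_epochs,
        "batch_size": clf.batch_size,
        "learning_rate": clf.learning_rate,
        "random_state": clf.random_state,
        "loss_curve": list(clf.loss_curve_),
        "numpy_version": np.__version__,
    }
    if kind == "densehead":
        meta["hidden"] = clf.hidden
    arrays = {f"param_{k}": v for k, v in clf.net_.params.items()}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        with open(tmp, "wb") as fh:
            np.savez(fh, meta=json.dumps(meta), **arrays)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_model(path):
    """Load a checkpoint back into a fitted classifier; forward outputs
    reproduce bit-exactly."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            arrays = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
    except (OSError, ValueError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as e:
        raise IntegrityError(f"cannot read checkpoint {path}: {e}") from e
    version = meta.get("schema_version")
    if version != CHECKPOINT_SCHEMA_VERSION:
        raise IntegrityError(
            f"checkpoint schema version {version} unsupported "
            f"(this build reads version {CHECKPOINT_SCHEMA_VERSION}); re-train or convert")
    cls = _KIND_TO_CLS[meta["kind"]]
    config = CapsNetConfig(**meta["config"])
    kw = dict(config=config, n_epochs=meta["n_epochs"], batch_size=meta["batch_size"],
              learning_rate=meta["learning_rate"], random_state=meta["random_state"])
    if meta["kind"] == "densehead":
        kw["hidden"] = meta["hidden"]
    clf = cls(**kw)
    clf.classes_ = np.array(meta["classes"])
    clf.config_ = config
    clf.loss_curve_ = meta["loss_curve"]
    from .capsnet import CapsNet, DenseHeadNet
    net_cls = DenseHeadNet if meta["kind"] == "densehead" else CapsNet
    if meta["kind"] == "densehead":
        clf.net_ = net_cls(config, params=arrays, hidden=meta["hidden"])
    else:
        clf.net_ = net_cls(config, params=arrays)
    clf.n_features_in_ = config.input_resolution ** 2
    return clf


# ---------------------------------------------------------------------------
# FCGR matrices and tables
# ---------------------------------------------------------------------------

def write_fcgr_text(image: FCGRImage, path) -> None:
    """One FCGR matrix as tab-delimited text (row 0 = top of the image)."""
    def _w(fh):
        fh.write(f"# resolution={image.resolution} total_points={image.total_points} "
                 f"normalization={image.normalization}\n")
        np.savetxt(fh, image.as_array(), fmt="%.10g", delimiter="\t")
    _atomic_write(path, _w)


def save_fcgr_stack(images: np.ndarray, ids, path, resolution: int,
                    normalization: str = "raw") -> None:
    """Stacked FCGR matrices with ids and metadata in one npz container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        with open(tmp, "wb") as fh:
            np.savez(fh, images=np.asarray(images), ids=np.array(list(ids), dtype=str),
                     resolution=resolution, normalization=normalization)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_fcgr_stack(path):
    with np.load(path, allow_pickle=False) as data:
        return (np.asarray(data["images"]), list(data["ids"]),
                int(data["resolution"]), str(data["normalization"]))


def export_fcgr_png(image: FCGRImage, path, cmap: str = "viridis") -> None:
    """Optional heatmap rendering for visual inspection (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image.as_array(), cmap=cmap)
    ax.set_xticks([])
    ax.set_yticks([])
    if image.record_id:
        ax.set_title(image.record_id, fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def write_tsv(df: pd.DataFrame, path) -> None:
    _atomic_write(path, lambda fh: df.to_csv(fh, sep="\t", index=False))


def write_json(obj, path) -> None:
    _atomic_write(path, lambda fh: json.dump(obj, fh, indent=2, sort_keys=True))
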