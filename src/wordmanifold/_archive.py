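"""Deterministic model archives.

A fitted model is stored as an uncompressed ZIP whose members are .npy
arrays plus one JSON header.  Member timestamps are pinned to the ZIP epoch
so that identical models produce byte-identical archives — reruns of the
same configuration and seed can be compared by checksum.
"""

from __future__ import annotations

import io
import json
import zipfile
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1
_EPOCH = (1980, 1, 1, 0, 0, 0)


def _write_member(zf: zipfile.ZipFile, name: str, data: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_EPOCH)
    info.compress_type = zipfile.ZIP_STORED
    info.external_attr = 0o644 << 16
    zf.writestr(info, data)


def _write_array(zf: zipfile.ZipFile, name: str, arr: np.ndarray) -> None:
    buf = io.BytesIO()
    np.save(buf, np.ascontiguousarray(arr))
    _write_member(zf, name + ".npy", buf.getvalue())


def _read_array(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    with zf.open(name + ".npy") as fh:
        return np.load(io.BytesIO(fh.read()), allow_pickle=False)


def save_model(model, path) -> None:
    path = Path(path)
    weights = model.weights
    if weights is None:
        raise ValueError("model has no retained weights; cannot serialize")
    n = model.n
    J = np.stack([lw.J for lw in weights])
    s_counts = np.array([lw.s for lw in weights], dtype=np.int64)
    W_concat = np.concatenate([lw.W for lw in weights], axis=1)  # (k, sum s)
    w_reg = np.stack([lw.w_reg for lw in weights])
    header = {
        "format_version": FORMAT_VERSION,
        "kind": "wordmanifold-model",
        "n": n,
        "dim": model.dim,
        "d": model.d,
        "k": model.k,
        "metric": model.metric,
        "gamma_scale": model.gamma_scale,
        "eta": model.eta,
        "eta_value": model.eta_value,
        "window_start": model.window_start,
        "vocab": model.vocab,
        "params": {key: val for key, val in model.params.items()},
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        _write_member(
            zf, "header.json",
            json.dumps(header, sort_keys=True, separators=(",", ":")).encode("utf-8"),
        )
        _write_array(zf, "X_train", model.X_train)
        _write_array(zf, "Y_train", model.Y_train)
        _write_array(zf, "eigvals", model.eigvals)
        _write_array(zf, "J", J)
        _write_array(zf, "s_counts", s_counts)
        _write_array(zf, "W_concat", W_concat)
        _write_array(zf, "w_reg", w_reg)
        if model.window_indices is not None:
            _write_array(zf, "window_indices", np.asarray(model.window_indices))


def load_model(cls, path):
    from .mlle import LocalWeights

    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        header = json.loads(zf.read("header.json").decode("utf-8"))
        if header.get("kind") != "wordmanifold-model":
            raise ValueError(f"{path} is not a wordmanifold model archive")
        if header["format_version"] > FORMAT_VERSION:
            raise ValueError(
                f"archive format {header['format_version']} is newer than supported"
            )
        X_train = _read_array(zf, "X_train")
        Y_train = _read_array(zf, "Y_train")
        eigvals = _read_array(zf, "eigvals")
        J = _read_array(zf, "J")
        s_counts = _read_array(zf, "s_counts")
        W_concat = _read_array(zf, "W_concat")
        w_reg = _read_array(zf, "w_reg")
        names = set(zf.namelist())
        window_indices = (
            _read_array(zf, "window_indices") if "window_indices.npy" in names else None
        )
    weights = []
    offset = 0
    k = J.shape[1]
    for i in range(header["n"]):
        s = int(s_counts[i])
        W = W_concat[:, offset : offset + s]
        offset += s
        weights.append(
            LocalWeights(
                J=J[i], singvals=np.zeros(k), r=k - s, s=s,
                w_reg=w_reg[i], V=np.zeros((k, 0)), alpha=np.nan,
                h=np.zeros(s), W=W, G=None,
            )
        )
    return cls(
        X_train=X_train, Y_train=Y_train, eigvals=eigvals,
        k=header["k"], d=header["d"], metric=header["metric"],
        gamma_scale=header["gamma_scale"], eta=header["eta"],
        eta_value=header["eta_value"], window_start=header["window_start"],
        window_indices=window_indices, vocab=header["vocab"],
        weights=weights, graph=None, params=header["params"],
    )
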