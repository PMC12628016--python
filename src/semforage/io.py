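"""Readers and writers for the pipeline's plain-text formats.

Formats: TSV tables (response logs, covariates, manifests, result tables),
word2vec plain-text embeddings (header ``n_words dim`` then one
``word v1 ... vd`` row per word), whitespace-delimited square connectivity
matrices (one file per subject, listed in a manifest TSV), and JSON results.
Result tables are written with ``#``-prefixed header lines recording the seed
and configuration hash; all readers skip such comment lines.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .synthetic import ConnectivityBundle

__all__ = [
    "read_response_log", "write_response_log",
    "read_embeddings", "write_embeddings",
    "read_matrix", "write_matrix",
    "read_node_labels", "write_node_labels",
    "read_manifest", "read_connectivity",
    "read_table", "write_table",
]

SPOKEN_COLUMNS = ["participant", "cue", "response_index", "word",
                  "onset", "offset", "meaning"]
TYPED_COLUMNS = ["participant", "cue", "response_index", "word",
                 "first_keypress", "validation", "n_chars", "meaning"]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None
                ) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_response_log(path, mode: str = "spoken") -> pd.DataFrame:
    """Read and validate a response-log TSV.

    Checks the required columns for the declared mode, strictly increasing
    response indices, non-decreasing timing, offset >= onset, and absence of
    duplicate (participant, cue, response_index) keys.  Returns the log
    sorted by key.
    """
    required = SPOKEN_COLUMNS if mode == "spoken" else TYPED_COLUMNS
    if mode not in ("spoken", "typed"):
        raise ValueError("mode must be 'spoken' or 'typed'")
    df = read_table(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"response log missing column(s): {missing}")
    df = df.sort_values(["participant", "cue", "response_index"],
                        kind="stable").reset_index(drop=True)
    dup = df.duplicated(["participant", "cue", "response_index"])
    if dup.any():
        r = df[dup].iloc[0]
        raise FormatError(f"duplicate (participant, cue, response_index): "
                          f"({r['participant']}, {r['cue']}, "
                          f"{r['response_index']})")
    grp = df.groupby(["participant", "cue"])
    if (grp["response_index"].diff().dropna() <= 0).any():
        raise FormatError("response_index not strictly increasing within a cue")
    time_col = "onset" if mode == "spoken" else "first_keypress"
    bad = grp[time_col].diff().dropna() < 0
    if bad.any():
        row = df.loc[bad[bad].index[0]]
        raise DataError(f"decreasing {time_col} at participant="
                        f"{row['participant']} cue={row['cue']} "
                        f"response_index={row['response_index']}")
    if mode == "spoken" and (df["offset"] < df["onset"]).any():
        row = df[df["offset"] < df["onset"]].iloc[0]
        raise DataError(f"offset < onset at participant={row['participant']} "
                        f"cue={row['cue']} response_index="
                        f"{row['response_index']}")
    return df


def write_response_log(df: pd.DataFrame, path,
                       header_lines: list[str] | None = None) -> None:
    write_table(df, path, header_lines)


def read_embeddings(path) -> dict[str, np.ndarray]:
    """Read word2vec plain-text embeddings.

    Expects a header line ``n_words dim`` followed by ``word v1 ... vd``
    rows.  Duplicate tokens keep the first occurrence (with a warning); a row
    with the wrong number of values raises a format error naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path.name}: expected header 'n_words dim'")
        try:
            n_words, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path.name}: non-integer header") from exc
        table: dict[str, np.ndarray] = {}
        dupes = 0
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            word, vals = parts[0], parts[1:]
            if len(vals) != dim:
                raise FormatError(f"{path.name}:{lineno}: expected {dim} "
                                  f"values, found {len(vals)}")
            if word in table:
                dupes += 1
                continue
            table[word] = np.asarray(vals, dtype=float)
    if dupes:
        warnings.warn(f"{dupes} duplicate token(s) in {path.name}; first "
                      f"occurrence kept")
    if len(table) != n_words:
        warnings.warn(f"{path.name}: header declares {n_words} words, "
                      f"read {len(table)}")
    return table


def write_embeddings(table, path) -> None:
    """Write embeddings in word2vec plain-text format."""
    items = table.embeddings.items() if hasattr(table, "embeddings") \
        else table.items()
    items = list(items)
    if not items:
        raise ValueError("cannot write an empty embedding table")
    dim = len(items[0][1])
    with open(path, "w") as fh:
        fh.write(f"{len(items)} {dim}\n")
        for word, vec in items:
            fh.write(word + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")


def read_matrix(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FormatError(f"{Path(path).name}: not a square matrix")
    return m


def write_matrix(m: np.ndarray, path) -> None:
    np.savetxt(path, m, fmt="%.8g")


def read_node_labels(path) -> dict[int, str]:
    df = read_table(path)
    for col in ("node_id", "network"):
        if col not in df.columns:
            raise FormatError(f"node-label table missing column {col!r}")
    return dict(zip(df["node_id"].astype(int), df["network"].astype(str)))


def write_node_labels(labels: dict[int, str], path) -> None:
    df = pd.DataFrame(sorted(labels.items()), columns=["node_id", "network"])
    write_table(df, path)


def read_manifest(path) -> pd.DataFrame:
    df = read_table(path)
    for col in ("subject_id", "path", "motion"):
        if col not in df.columns:
            raise FormatError(f"manifest missing column {col!r}")
    return df


def read_connectivity(manifest_path, labels_path) -> list[ConnectivityBundle]:
    """Load per-subject matrices listed in a manifest TSV plus node labels."""
    manifest = read_manifest(manifest_path)
    labels = read_node_labels(labels_path)
    base = Path(manifest_path).parent
    bundles = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        m = read_matrix(p)
        bundles.append(ConnectivityBundle(str(row["subject_id"]), m, labels,
                                          float(row["motion"])))
    return bundles
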