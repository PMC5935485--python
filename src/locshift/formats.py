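"""File formats: single-cell tables, profile/z matrices, config, manifests.

Everything is plain tab-separated text with ``NA`` for missing values so
intermediate results stay inspectable.  Matrix headers encode
screen, feature and bin (e.g. ``RAP60:f2_b3`` = feature 2, bud stage 3 of
the RAP60 screen); write/read round-trips are lossless including missing
masks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profiles import CELL_COLUMNS, CELL_TYPES, FEATURE_COLUMNS, PROFILE_LEN

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


def read_single_cell_table(path) -> pd.DataFrame:
    """Read and validate a single-cell TSV.

    Malformed rows (bad cell type, out-of-range stage, non-finite features,
    negative GFP) are rejected with line-numbered log messages and a summary;
    a missing required column raises naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "screen_id": str, "cell_id": str})
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    if len(df) == 0:
        logger.warning("%s: empty single-cell table", path)
        return df[CELL_COLUMNS]
    ok = np.ones(len(df), dtype=bool)
    reasons = {}

    def reject(mask, why):
        for line in np.where(mask & ok)[0]:
            logger.warning("%s line %d: %s", path, line + 2, why)  # +2: header + 1-based
        reasons[why] = int((mask & ok).sum())
        ok[np.asarray(mask)] = False

    stage = pd.to_numeric(df["stage_keypoint"], errors="coerce")
    reject(stage.isna() | (stage < 1) | (stage > 10), "stage_keypoint outside 1..10")
    reject(~df["cell_type"].isin(CELL_TYPES), "cell_type not mother/bud")
    feats = df[FEATURE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    reject(~np.isfinite(feats.to_numpy(dtype=float)).all(axis=1), "non-finite feature value")
    gfp = pd.to_numeric(df["gfp_intensity"], errors="coerce")
    reject(gfp.isna() | (gfp < 0), "gfp_intensity missing or negative")
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("%s: rejected %d of %d rows (%s)", path, dropped, len(df), reasons)
    out = df.loc[ok, CELL_COLUMNS].copy()
    out["stage_keypoint"] = out["stage_keypoint"].astype(int)
    return out.reset_index(drop=True)


def write_single_cell_table(cells: pd.DataFrame, path):
    cells[CELL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def write_matrix(matrix: pd.DataFrame, path):
    """Write a proteins x features matrix as TSV with NA for missing."""
    matrix.to_csv(path, sep="\t", index=True, na_rep=NA_TOKEN, index_label="protein_id")


def read_matrix(path, expect_screens: int | None = None) -> pd.DataFrame:
    """Read a profile/z matrix; optionally enforce 50 columns per screen."""
    df = pd.read_csv(path, sep="\t", index_col="protein_id", na_values=[NA_TOKEN])
    if expect_screens is not None and df.shape[1] != expect_screens * PROFILE_LEN:
        raise ValueError(
            f"{path}: expected {expect_screens} x {PROFILE_LEN} = "
            f"{expect_screens * PROFILE_LEN} columns, found {df.shape[1]}"
        )
    return df


def write_edges(edges, path):
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_edges(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.itertuples(index=False, name=None))


def read_annotations(path) -> dict[str, list[str]]:
    """term<TAB>protein map -> {term: [proteins]}"""
    df = pd.read_csv(path, sep="\t", dtype=str, names=["term", "protein"], header=0)
    out: dict[str, list[str]] = {}
    for term, protein in df.itertuples(index=False):
        out.setdefault(term, []).append(protein)
    return out


def config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def write_manifest(path, config: dict, outputs: dict[str, str], seed: int):
    """Sidecar provenance record for a pipeline run."""
    manifest = {
        "config_hash": config_hash(config),
        "seed": seed,
        "config": config,
        "outputs": outputs,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
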