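"""Readers and writers for the on-disk formats the pipeline exchanges.

Counts travel as a MatrixMarket trio (matrix.mtx + genes.tsv + barcodes.tsv,
optionally metadata.tsv); images as multi-page TIFF (one page per channel)
with a channels.json naming the pages; labeled ROI masks as integer TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

from .containers import CountMatrix


def read_counts_dir(path) -> CountMatrix:
    """Read a MatrixMarket trio directory into a CountMatrix.

    Expects ``matrix.mtx`` (genes × cells), ``genes.tsv``, ``barcodes.tsv``
    and, if present, ``metadata.tsv`` (tab-separated, one row per cell).
    """
    path = Path(path)
    X = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].to_numpy()
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    meta_path = path / "metadata.tsv"
    obs = (
        pd.read_csv(meta_path, sep="\t", index_col=0)
        if meta_path.exists()
        else pd.DataFrame()
    )
    return CountMatrix(X=X, genes=genes, barcodes=barcodes, obs=obs)


def write_counts_dir(counts: CountMatrix, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(counts.X))
    pd.Series(counts.genes).to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.barcodes).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if counts.obs.shape[1] > 0:
        counts.obs.to_csv(path / "metadata.tsv", sep="\t")


def write_image(image: np.ndarray, channels: list[str], path, channels_json=None) -> None:
    """Write a channels × rows × cols stack as a multi-page TIFF.

    ``channels.json`` (page order → channel name) is written next to the
    TIFF unless an explicit path is given.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if image.ndim != 3 or image.shape[0] != len(channels):
        raise ValueError("image must be channels x rows x cols matching channel names")
    tifffile.imwrite(path, image)
    cj = Path(channels_json) if channels_json else path.with_suffix(".channels.json")
    cj.write_text(json.dumps({"channels": list(channels)}, indent=2))


def read_image(path, channels_json=None) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    image = tifffile.imread(path)
    if image.ndim == 2:
        image = image[None]
    cj = Path(channels_json) if channels_json else path.with_suffix(".channels.json")
    if cj.exists():
        channels = json.loads(cj.read_text())["channels"]
    else:
        channels = [f"ch{i}" for i in range(image.shape[0])]
    if len(channels) != image.shape[0]:
        raise ValueError("channel names do not match image pages")
    return image, channels


def write_mask(mask: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, mask.astype(np.int32))


def read_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)).astype(np.int64)
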