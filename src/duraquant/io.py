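"""Readers and writers for the pipeline's on-disk formats.

Images travel as multi-page TIFF (one page per channel) with a JSON sidecar
recording pixel size and channel roles; masks as single-channel 0/255 TIFF;
allele tables as tidy TSV (``allele_id  allele_seq  organ  umi_count``);
expression as MTX plus features/barcodes/cell-label TSVs; landmark pairs as
CSV ``moving_row,moving_col,fixed_row,fixed_col``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from anndata import AnnData
from scipy import io as scio
from scipy import sparse

from duraquant.clonal import AlleleTable
from duraquant.spatial import WholeMountImage


def write_whole_mount(image: WholeMountImage, tiff_path: str | Path) -> Path:
    tiff_path = Path(tiff_path)
    names = list(image.channels)
    stack = np.stack([image.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(tiff_path, stack)
    sidecar = tiff_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "pixel_size": image.pixel_size,
                "channels": names,
                "channel_roles": {n: image.channel_roles[n] for n in names},
                "sample_id": image.sample_id,
                "group": image.group,
            },
            indent=2,
        )
    )
    return sidecar


def read_whole_mount(tiff_path: str | Path) -> WholeMountImage:
    tiff_path = Path(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    stack = tifffile.imread(tiff_path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {n: stack[i] for i, n in enumerate(meta["channels"])}
    return WholeMountImage(
        channels=channels,
        pixel_size=meta["pixel_size"],
        channel_roles=meta["channel_roles"],
        sample_id=meta.get("sample_id", ""),
        group=meta.get("group", ""),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def read_landmark_pairs(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    required = ["moving_row", "moving_col", "fixed_row", "fixed_col"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns {missing}")
    return (
        df[["moving_row", "moving_col"]].to_numpy(float),
        df[["fixed_row", "fixed_col"]].to_numpy(float),
    )


def write_allele_table(table: AlleleTable, path: str | Path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False)


def read_allele_table(
    path: str | Path, mouse_id: str = "", induction: str = ""
) -> AlleleTable:
    long = pd.read_csv(path, sep="\t")
    return AlleleTable.from_long(long, mouse_id=mouse_id, induction=induction)


def write_expression(adata: AnnData, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scio.mmwrite(out_dir / "matrix.mtx", X.T.tocoo())  # genes x cells, 10x layout
    adata.var.reset_index().to_csv(
        out_dir / "features.tsv", sep="\t", index=False, header=True
    )
    pd.Series(adata.obs_names, name="barcode").to_csv(
        out_dir / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.reset_index(names="barcode").to_csv(
        out_dir / "cell_labels.tsv", sep="\t", index=False
    )


def read_expression(in_dir: str | Path) -> AnnData:
    in_dir = Path(in_dir)
    X = sparse.csr_matrix(scio.mmread(in_dir / "matrix.mtx").T)
    var = pd.read_csv(in_dir / "features.tsv", sep="\t").set_index("gene")
    obs = pd.read_csv(in_dir / "cell_labels.tsv", sep="\t").set_index("barcode")
    return AnnData(X=X, obs=obs, var=var)


def read_gene_set(path: str | Path) -> list[str]:
    """One gene name per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
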