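"""On-disk layout: MatrixMarket count matrices, TSV metadata, JSON manifests.

A dataset directory contains spliced.mtx / unspliced.mtx (MatrixMarket
coordinate, genes x cells), genes.tsv, cells.tsv (cell_id, condition,
population, animal[, latent_time]), embedding.tsv and optionally
spatial.tsv.  Manifests are plain JSON with sorted keys and no timestamps,
so reruns with identical config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .synthetic import SplicedUnsplicedDataset


def _write_mtx(path: Path, mat: np.ndarray) -> None:
    m = sparse.coo_matrix(mat)
    if np.issubdtype(mat.dtype, np.integer):
        spio.mmwrite(str(path), m, field="integer")
    else:
        spio.mmwrite(str(path), m)


def write_dataset(ds: SplicedUnsplicedDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_mtx(out / "spliced.mtx", ds.spliced)
    _write_mtx(out / "unspliced.mtx", ds.unspliced)
    ds.gene_meta.to_csv(out / "genes.tsv", sep="\t", index=False)
    ds.cell_meta.to_csv(out / "cells.tsv", sep="\t", index=False)
    pd.DataFrame(ds.embedding, columns=["dim1", "dim2"]).assign(
        cell_id=ds.cell_meta["cell_id"].to_numpy()
    )[["cell_id", "dim1", "dim2"]].to_csv(out / "embedding.tsv", sep="\t", index=False)


def read_dataset(indir: str | Path) -> SplicedUnsplicedDataset:
    ind = Path(indir)
    spliced = np.asarray(spio.mmread(ind / "spliced.mtx").todense())
    unspliced = np.asarray(spio.mmread(ind / "unspliced.mtx").todense())
    gene_meta = pd.read_csv(ind / "genes.tsv", sep="\t")
    cell_meta = pd.read_csv(ind / "cells.tsv", sep="\t")
    emb = pd.read_csv(ind / "embedding.tsv", sep="\t")
    return SplicedUnsplicedDataset(
        spliced=spliced,
        unspliced=unspliced,
        cell_meta=cell_meta,
        embedding=emb[["dim1", "dim2"]].to_numpy(dtype=float),
        gene_meta=gene_meta,
    )


def write_spatial(cells: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cells.to_csv(path, sep="\t", index=False)


def read_spatial(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_triplets(
    path: str | Path, values: np.ndarray, neighbor_idx: np.ndarray,
    rows: np.ndarray, cell_ids: np.ndarray,
) -> None:
    """Sparse coordinate-triplet TSV for a per-population cc or tp block."""
    src = np.repeat(np.asarray(cell_ids)[rows], values.shape[1])
    tgt = np.asarray(cell_ids)[neighbor_idx[rows].ravel()]
    pd.DataFrame({"source_cell": src, "target_cell": tgt, "value": values.ravel()}).to_csv(
        path, sep="\t", index=False
    )


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def checksum_dir(outdir: str | Path, patterns: tuple[str, ...] = ("*.tsv", "*.mtx", "*.json")) -> dict[str, str]:
    out = Path(outdir)
    sums = {}
    for pat in patterns:
        for p in sorted(out.rglob(pat)):
            if p.name == "manifest.json":
                continue
            sums[str(p.relative_to(out))] = sha256_file(p)
    return sums


def validate_inputs(data_dir: str | Path) -> dict:
    """Structural validation of a dataset directory.

    Checks MatrixMarket headers, dimension agreement between the two count
    matrices and the metadata tables, completeness of population labels and
    presence of both conditions.  Returns a machine-readable report; all
    failures are collected, none raised.
    """
    ind = Path(data_dir)
    failures: list[str] = []
    checks: list[str] = []

    def check(name: str, ok: bool, detail: str = "") -> None:
        checks.append(name)
        if not ok:
            failures.append(f"{name}: {detail}" if detail else name)

    dims = {}
    for name in ("spliced", "unspliced"):
        path = ind / f"{name}.mtx"
        if not path.exists():
            check(f"{name}.mtx present", False, "missing file")
            continue
        try:
            info = spio.mminfo(path)
            dims[name] = (info[0], info[1])
            check(f"{name}.mtx header", True)
        except Exception as exc:  # malformed header
            check(f"{name}.mtx header", False, str(exc))
    if len(dims) == 2:
        check(
            "spliced/unspliced dimensions agree",
            dims["spliced"] == dims["unspliced"],
            f"{dims['spliced']} vs {dims['unspliced']}",
        )

    cells = genes = None
    if (ind / "cells.tsv").exists():
        cells = pd.read_csv(ind / "cells.tsv", sep="\t")
        check("cells.tsv present", True)
    else:
        check("cells.tsv present", False, "missing file")
    if (ind / "genes.tsv").exists():
        genes = pd.read_csv(ind / "genes.tsv", sep="\t")
        check("genes.tsv present", True)
    else:
        check("genes.tsv present", False, "missing file")

    if cells is not None and "spliced" in dims:
        check(
            "cell count matches matrix columns",
            len(cells) == dims["spliced"][1],
            f"{len(cells)} cells vs {dims['spliced'][1]} columns",
        )
    if genes is not None and "spliced" in dims:
        check(
            "gene count matches matrix rows",
            len(genes) == dims["spliced"][0],
            f"{len(genes)} genes vs {dims['spliced'][0]} rows",
        )
    if cells is not None:
        check(
            "population labels complete",
            "population" in cells and cells["population"].notna().all(),
            "missing population labels",
        )
        check(
            "both conditions present",
            "condition" in cells and cells["condition"].nunique() >= 2,
            "fewer than 2 conditions",
        )
    if (ind / "embedding.tsv").exists():
        emb = pd.read_csv(ind / "embedding.tsv", sep="\t")
        if cells is not None:
            check(
                "embedding covers all cells",
                len(emb) == len(cells)
                and set(emb["cell_id"]) == set(cells["cell_id"]),
                "embedding/cells mismatch",
            )
    else:
        check("embedding.tsv present", False, "missing file")

    return {"ok": not failures, "checks": checks, "failures": failures}
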