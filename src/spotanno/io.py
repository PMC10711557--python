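"""Readers and writers for expression matrices, coordinates and marker lists.

Supported formats
-----------------
Expression : dense CSV/TSV (spots as rows, header = gene ids, first column =
    spot id) or a MatrixMarket triplet (``matrix.mtx`` spots x genes, with
    ``genes.tsv`` and ``barcodes.tsv`` alongside).
Coordinates : CSV with columns ``spot_id,x,y``.
Markers : CSV with columns ``type,gene``, or JSON ``{type: [genes]}``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import MarkerMap, RawExpression, SpotCoordinates


def read_expression(path: str | Path, format: str = "csv") -> RawExpression:
    """Read a spot-by-gene expression matrix.

    Parameters
    ----------
    path
        For ``csv``/``tsv``: the file itself.  For ``mtx_triplet``: either the
        ``.mtx`` file or the directory holding ``matrix.mtx``, ``genes.tsv``
        and ``barcodes.tsv``.
    format
        ``"csv"``, ``"tsv"`` or ``"mtx_triplet"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression input not found: {path}")
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            seen: set[str] = set()
            dup = next(g for g in header if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id in header: {dup!r}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        gene_ids = [str(g) for g in df.columns]
        return RawExpression(
            counts=df.to_numpy(dtype=float),
            gene_ids=gene_ids,
            spot_ids=[str(s) for s in df.index],
        )
    if format == "mtx_triplet":
        if path.is_dir():
            mtx, genes_f, bars_f = (path / "matrix.mtx", path / "genes.tsv",
                                    path / "barcodes.tsv")
        else:
            mtx = path
            genes_f = path.parent / "genes.tsv"
            bars_f = path.parent / "barcodes.tsv"
        for f in (mtx, genes_f, bars_f):
            if not f.exists():
                raise FileNotFoundError(f"mtx triplet member missing: {f}")
        try:
            mat = scipy.io.mmread(mtx)
        except Exception as exc:
            raise ValueError(f"failed to parse {mtx}: {exc}") from exc
        counts = np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float)
        gene_ids = _read_id_column(genes_f)
        spot_ids = _read_id_column(bars_f)
        return RawExpression(counts=counts, gene_ids=gene_ids, spot_ids=spot_ids)
    raise ValueError(f"unknown expression format: {format!r}")


def write_expression(raw: RawExpression, path: str | Path,
                     format: str = "csv") -> None:
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(raw.counts, index=raw.spot_ids, columns=raw.gene_ids)
        df.to_csv(path, sep=sep, index_label="spot_id")
    elif format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx",
                         scipy.sparse.coo_matrix(raw.counts))
        (path / "genes.tsv").write_text("\n".join(raw.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(raw.spot_ids) + "\n")
    else:
        raise ValueError(f"unknown expression format: {format!r}")


def read_coordinates(path: str | Path) -> SpotCoordinates:
    """Read a ``spot_id,x,y`` CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    df = pd.read_csv(path)
    for col in ("spot_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return SpotCoordinates(
        spot_ids=[str(s) for s in df["spot_id"]],
        xy=df[["x", "y"]].to_numpy(dtype=float),
    )


def write_coordinates(coords: SpotCoordinates, path: str | Path) -> None:
    pd.DataFrame({
        "spot_id": coords.spot_ids,
        "x": coords.xy[:, 0],
        "y": coords.xy[:, 1],
    }).to_csv(path, index=False)


def read_markers(path: str | Path) -> MarkerMap:
    """Read a marker list (CSV ``type,gene`` or JSON ``{type: [genes]}``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"marker file not found: {path}")
    if path.suffix.lower() == ".json":
        mapping = json.loads(path.read_text())
        if not isinstance(mapping, dict):
            raise ValueError(f"{path}: JSON markers must be an object")
        pairs = [(str(t), str(g)) for t, genes in mapping.items()
                 for g in genes]
    else:
        df = pd.read_csv(path)
        for col in ("type", "gene"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        pairs = [(str(t), str(g)) for t, g in zip(df["type"], df["gene"])]
    return marker_map_from_pairs(pairs)


def write_markers(markers: MarkerMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        mapping = {
            t: [markers.marker_gene_ids[j]
                for j in np.flatnonzero(markers.rho[:, k])]
            for k, t in enumerate(markers.type_names)
        }
        path.write_text(json.dumps(mapping, indent=1) + "\n")
    else:
        rows = [(t, markers.marker_gene_ids[j])
                for k, t in enumerate(markers.type_names)
                for j in np.flatnonzero(markers.rho[:, k])]
        pd.DataFrame(rows, columns=["type", "gene"]).to_csv(path, index=False)


def _read_id_column(path: Path) -> list[str]:
    """First whitespace-delimited field of every non-empty line."""
    return [line.split("\t")[0].split()[0]
            for line in path.read_text().splitlines() if line.strip()]


def marker_map_from_pairs(pairs: list[tuple[str, str]]) -> MarkerMap:
    """Build a MarkerMap from (type, gene) pairs, preserving first-seen order."""
    type_names: list[str] = []
    gene_ids: list[str] = []
    for t, g in pairs:
        if t not in type_names:
            type_names.append(t)
        if g not in gene_ids:
            gene_ids.append(g)
    rho = np.zeros((len(gene_ids), len(type_names)), dtype=np.int8)
    for t, g in pairs:
        rho[gene_ids.index(g), type_names.index(t)] = 1
    return MarkerMap(rho=rho, marker_gene_ids=gene_ids, type_names=type_names)
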