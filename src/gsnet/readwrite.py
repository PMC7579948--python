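"""File interfaces: GMT / plain-text genesets, edge lists, and result CSVs.

Results are plain RFC-4180 CSV with a fixed header and no timestamps, so a
run is byte-reproducible from its seed. Floats are written with 12
significant digits, enough for a lossless round trip at the precision the
statistics carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import TestResult
from .netcore import Network

RESULT_COLUMNS = [
    "geneset", "geneset_b", "statistic", "observed", "n_mapped", "m_mapped",
    "null_mean", "null_sd", "pvalue", "tail", "n_samples", "sampler", "mode",
    "seed",
]

FLOAT_FORMAT = "%.12g"


@dataclass
class GenesetRecord:
    """One GMT entry: a named gene list not yet mapped to any network."""

    name: str
    description: str
    genes: tuple[str, ...]


# ---------------------------------------------------------------------------
# genesets


def read_gmt(path: str | Path) -> list[GenesetRecord]:
    """Read a Gene Matrix Transposed file (name, description, genes...)."""
    path = Path(path)
    records: list[GenesetRecord] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one gene (tab-separated)"
                )
            name = fields[0].strip()
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate geneset name {name!r}")
            seen.add(name)
            genes = tuple(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            records.append(GenesetRecord(name, fields[1].strip(), genes))
    if not records:
        raise ValueError(f"{path}: no genesets found")
    return records


def write_gmt(records: Iterable[GenesetRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write("\t".join([rec.name, rec.description, *rec.genes]) + "\n")


def read_txt_geneset(path: str | Path, name: str | None = None) -> GenesetRecord:
    """Read a plain-text geneset: one gene id per line, blanks skipped."""
    path = Path(path)
    genes: list[str] = []
    with path.open() as fh:
        for raw in fh:
            g = raw.strip()
            if g:
                genes.append(g)
    if not genes:
        raise ValueError(f"{path}: no genes found")
    return GenesetRecord(name or path.stem, "", tuple(dict.fromkeys(genes)))


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write a network as a two-column tab-separated edge list."""
    ii, jj = np.nonzero(np.triu(net.adjacency))
    with Path(path).open("w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{net.nodes[i]}\t{net.nodes[j]}\n")


# ---------------------------------------------------------------------------
# result tables


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results], columns=RESULT_COLUMNS)


def write_results(results_or_frame, path: str | Path) -> None:
    """Write test results (or any result frame) to CSV."""
    if isinstance(results_or_frame, pd.DataFrame):
        frame = results_or_frame
    else:
        frame = results_to_frame(results_or_frame)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[""])
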