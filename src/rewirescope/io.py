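"""Tab-separated readers and writers for the pipeline's file formats.

All matrices are genes-as-rows TSV with a header of sample/construct ids and
the gene id in the first column; networks are three-column edge lists
(``regulator<TAB>target<TAB>sign``); floats are written with 6 significant
digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConstructDesign, ExpressionMatrix, GoldStandardNetwork

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_expression",
    "read_expression",
    "write_design",
    "read_design",
    "write_network",
    "read_network",
]

FLOAT_FMT = "%.6g"


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=df.index.name or "gene")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: ExpressionMatrix, prefix) -> tuple:
    """Write the replicate matrix and its sample sheet; returns the two paths."""
    prefix = Path(prefix)
    mpath = prefix.with_suffix(".tsv")
    spath = prefix.parent / (prefix.name + ".samples.tsv")
    write_matrix(matrix.data, mpath)
    sheet = pd.DataFrame(
        {
            "construct": matrix.sample_construct.reindex(matrix.samples),
            "control": matrix.is_control.reindex(matrix.samples).astype(int),
        }
    )
    sheet.to_csv(spath, sep="\t", index_label="sample")
    return mpath, spath


def read_expression(matrix_path, samples_path=None, control_label=None) -> ExpressionMatrix:
    """Read a replicate matrix; sample->construct comes from the sample sheet
    or, failing that, by stripping a ``_rN`` replicate suffix, with control
    samples identified by ``control_label``."""
    data = read_matrix(matrix_path)
    if samples_path is not None:
        sheet = pd.read_csv(samples_path, sep="\t", index_col=0)
        construct = sheet["construct"]
        control = sheet["control"].astype(bool)
    else:
        construct = pd.Series(
            {s: s.rsplit("_r", 1)[0] for s in data.columns}, name="construct"
        )
        control = construct == control_label
    return ExpressionMatrix(data=data, sample_construct=construct, is_control=control)


def write_design(designs: list, path) -> None:
    rows = [
        {
            "construct": d.construct,
            "promoter": d.promoter,
            "orf": d.orf if d.orf is not None else "",
            "promoter_strength": d.promoter_strength,
            "orf_out_degree": d.orf_out_degree,
        }
        for d in designs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_design(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    designs = []
    for _, row in df.iterrows():
        orf = row["orf"] or None
        designs.append(
            ConstructDesign(
                construct=row["construct"],
                promoter=row["promoter"],
                orf=orf,
                promoter_strength=float(row["promoter_strength"]),
                orf_out_degree=int(row["orf_out_degree"]) if orf is not None else 0,
            )
        )
    return designs


def write_network(network: GoldStandardNetwork, path, weights: bool = False) -> None:
    with open(path, "w") as fh:
        if weights:
            fh.write("regulator\ttarget\tsign\tweight\n")
            for r, t, s, w in network.edges:
                fh.write(f"{r}\t{t}\t{s}\t{w:.6g}\n")
        else:
            fh.write("regulator\ttarget\tsign\n")
            for r, t, s, _ in network.edges:
                fh.write(f"{r}\t{t}\t{s}\n")


def read_network(path) -> GoldStandardNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = []
    for _, row in df.iterrows():
        weight = float(row["weight"]) if "weight" in df.columns else 1.0
        sign = int(row["sign"]) if "sign" in df.columns else 1
        edges.append((row["regulator"], row["target"], sign, weight))
    return GoldStandardNetwork(
        regulators=frozenset(df["regulator"]), edges=tuple(edges)
    )
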