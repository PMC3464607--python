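"""File formats: intensity tables, FASTA/FASTQ, parameter and config files.

The intensity table is a tab-separated file with header
``cluster_id  cycle  A  C  G  T``: one row per (cluster, cycle), cycles
contiguous from 1, channel order fixed A, C, G, T.  Truth sequences travel
as FASTA and called sequences as FASTQ with phred+33 qualities (both via
Biopython).  Parameter sets and run configuration are YAML key-value files
with strict schemas (unknown keys are rejected).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .params import (
    CycleParams,
    IntensityRead,
    ParameterSet,
    PhasingParams,
    TemplateSequence,
)

__all__ = [
    "read_intensities",
    "write_intensities",
    "write_truth_fasta",
    "read_truth_fasta",
    "write_fastq",
    "read_fastq",
    "write_params",
    "read_params",
    "load_config",
]

_CHANNELS = ["A", "C", "G", "T"]
_COLUMNS = ["cluster_id", "cycle"] + _CHANNELS


def write_intensities(reads: Sequence[IntensityRead], path) -> None:
    """Serialize reads to the tab-separated intensity table.

    Deterministic: 12 significant digits, clusters in input order.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for rd in reads:
            for t in range(1, rd.L + 1):
                vals = "\t".join(f"{v:.12g}" for v in rd.y[t - 1])
                fh.write(f"{rd.cluster_id}\t{t}\t{vals}\n")


def read_intensities(path) -> list[IntensityRead]:
    """Parse the intensity table; one IntensityRead per cluster.

    Enforces contiguous cycles 1..L within each cluster and a common L
    across clusters; malformed rows raise :class:`ParseError` naming the
    offending cluster.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str})
    except Exception as exc:
        raise ParseError(f"cannot parse intensity table {path}: {exc}") from exc
    if list(df.columns) != _COLUMNS:
        raise ParseError(
            f"intensity table must have columns {_COLUMNS}, got {list(df.columns)}"
        )
    if df.empty:
        raise ParseError(f"intensity table {path} contains no clusters")
    for col in ["cycle"] + _CHANNELS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ParseError(f"non-numeric value in column {col}, row {bad + 2}")
    reads: list[IntensityRead] = []
    L_ref: int | None = None
    for cid, grp in df.groupby("cluster_id", sort=False):
        grp = grp.sort_values("cycle")
        cycles = grp["cycle"].to_numpy()
        L = len(cycles)
        if not np.array_equal(cycles, np.arange(1, L + 1)):
            raise ParseError(f"cluster {cid}: cycles not contiguous 1..L")
        if L_ref is None:
            L_ref = L
        elif L != L_ref:
            raise ParseError(
                f"cluster {cid}: ragged length {L} (expected {L_ref})"
            )
        reads.append(IntensityRead(y=grp[_CHANNELS].to_numpy(float), cluster_id=str(cid)))
    if not reads:
        raise ParseError(f"intensity table {path} contains no clusters")
    return reads


def write_truth_fasta(
    truths: Sequence[TemplateSequence], path, ids: Sequence[str] | None = None
) -> None:
    """Write template sequences as FASTA (line width 70)."""
    if ids is None:
        ids = [f"cluster{i:05d}" for i in range(len(truths))]
    records = [
        SeqRecord(Seq(str(t)), id=str(i), description="") for i, t in zip(ids, truths)
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=70).write_file(records)


def read_truth_fasta(path) -> tuple[list[str], list[TemplateSequence]]:
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(TemplateSequence.from_string(str(rec.seq)))
    return ids, seqs


def write_fastq(results: Sequence, ids: Sequence[str], path) -> None:
    """Write call results as FASTQ with phred+33 quality encoding."""
    records = []
    for res, cid in zip(results, ids):
        phred = np.asarray(res.phred, dtype=int)
        if phred.min() < 0 or phred.max() > 93:
            raise ValueError(
                f"phred scores for {cid} outside the encodable range 0..93"
            )
        rec = SeqRecord(Seq(res.calls), id=str(cid), description="")
        rec.letter_annotations["phred_quality"] = phred.tolist()
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path) -> tuple[list[str], list[str], list[np.ndarray]]:
    ids, seqs, quals = [], [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        quals.append(np.array(rec.letter_annotations["phred_quality"], dtype=int))
    return ids, seqs, quals


# ---------------------------------------------------------------------------
# parameter and config files

_WINDOW_KEYS = {"d_mean", "d_var", "sigma_mean", "sigma_var", "alpha", "K", "Sigma"}
_PARAM_KEYS = {"p", "q", "window_length", "read_length", "windows"}


def write_params(params: ParameterSet, path) -> None:
    """Serialize a ParameterSet as a YAML key-value file.

    Matrices are stored as 16 numbers row-major.
    """
    doc = {
        "p": float(params.phasing.p),
        "q": float(params.phasing.q),
        "window_length": int(params.window_length),
        "read_length": int(params.L),
        "windows": [
            {
                "d_mean": float(cp.d_mean),
                "d_var": float(cp.d_var),
                "sigma_mean": float(cp.sigma_mean),
                "sigma_var": float(cp.sigma_var),
                "alpha": float(cp.alpha),
                "K": [float(v) for v in cp.K.ravel()],
                "Sigma": [float(v) for v in cp.Sigma.ravel()],
            }
            for cp in params.per_window
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_params(path) -> ParameterSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"parameter file {path} is not a mapping")
    unknown = set(doc) - _PARAM_KEYS
    if unknown:
        raise ParseError(f"unknown keys in parameter file: {sorted(unknown)}")
    missing = _PARAM_KEYS - set(doc)
    if missing:
        raise ParseError(f"missing keys in parameter file: {sorted(missing)}")
    windows = []
    for i, wdoc in enumerate(doc["windows"]):
        bad = set(wdoc) - _WINDOW_KEYS
        if bad:
            raise ParseError(f"unknown keys in window {i}: {sorted(bad)}")
        windows.append(
            CycleParams(
                d_mean=float(wdoc["d_mean"]),
                d_var=float(wdoc.get("d_var", 0.0)),
                sigma_mean=float(wdoc["sigma_mean"]),
                sigma_var=float(wdoc.get("sigma_var", 0.0)),
                alpha=float(wdoc["alpha"]),
                K=np.asarray(wdoc["K"], dtype=float).reshape(4, 4),
                Sigma=np.asarray(wdoc["Sigma"], dtype=float).reshape(4, 4),
            )
        )
    return ParameterSet(
        PhasingParams(float(doc["p"]), float(doc["q"])),
        tuple(windows),
        int(doc["window_length"]),
        int(doc["read_length"]),
    )


def load_config(path, allowed: set[str], required: set[str]) -> dict:
    """Load a YAML config with a strict key schema (typo safety)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ParseError(f"config {path} is not a mapping")
    unknown = set(doc) - allowed
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    missing = required - set(doc)
    if missing:
        raise ParseError(f"missing config keys: {sorted(missing)}")
    return doc
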