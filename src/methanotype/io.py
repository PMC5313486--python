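"""Readers and writers for the pipeline's plain-text formats.

Gas logs: CSV with columns ``session_id,cow_id,t_s,ch4_mg_per_kg``.
OTU tables: counts TSV (rows = otu_id, columns = ``cow_period_replicate``
libraries), taxonomy TSV (otu_id, lineage, domain, clade) and a sample
metadata TSV.  qPCR: one CSV holding standard and sample wells.  Config:
one YAML file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .community import OtuTable
from .sniffer import GasTrace

__all__ = [
    "traces_to_frame",
    "frame_to_traces",
    "write_gas_log",
    "read_gas_log",
    "write_otu_table",
    "read_otu_table",
    "write_qpcr",
    "read_qpcr",
    "read_config",
    "write_config",
]


def traces_to_frame(traces) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "session_id": tr.session_id,
                "cow_id": tr.cow_id,
                "t_s": tr.t,
                "ch4_mg_per_kg": tr.c,
            }
        )
        for tr in traces
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[GasTrace]:
    traces = []
    for (session, cow), sub in df.groupby(["session_id", "cow_id"], sort=True):
        sub = sub.sort_values("t_s")
        traces.append(
            GasTrace(
                cow_id=str(cow),
                session_id=str(session),
                t=sub["t_s"].to_numpy(),
                c=sub["ch4_mg_per_kg"].to_numpy(),
            )
        )
    return traces


def write_gas_log(traces, path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_gas_log(path) -> list[GasTrace]:
    return frame_to_traces(pd.read_csv(path))


def write_otu_table(table: OtuTable, counts_path, taxonomy_path, samples_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.taxonomy.to_csv(taxonomy_path, sep="\t")
    table.samples.to_csv(samples_path, sep="\t")


def read_otu_table(counts_path, taxonomy_path, samples_path) -> OtuTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    taxonomy["clade"] = taxonomy["clade"].fillna("")
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return OtuTable(counts=counts, samples=samples, taxonomy=taxonomy)


def write_qpcr(standards: pd.DataFrame, samples: pd.DataFrame, path) -> None:
    cols = ["well", "target", "kind", "copies", "cow_id", "period", "dilution", "cq"]
    combined = pd.concat([standards, samples], ignore_index=True).reindex(columns=cols)
    combined.to_csv(path, index=False)


def read_qpcr(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path)
    standards = df[df["kind"] == "standard"].dropna(axis=1, how="all")
    samples = df[df["kind"] == "sample"].dropna(axis=1, how="all")
    return standards.reset_index(drop=True), samples.reset_index(drop=True)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
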