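"""Readers and writers for the plain-text formats the pipeline touches.

Count matrices and annotations are TSV; HTSeq-count per-sample files are
two-column TSV; protein lists are one-identifier-per-line CSV; PSM tables
are TSV; Elispot tables are CSV; gene sets are GMT (see
:class:`secrenet.enrichment.GeneSetCollection`); networks are edge-list or
HIPPIE TSV (see :func:`secrenet.network.load_network`).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .degs import CountStudy
from .network import PPINetwork
from .proteomics import FractionProteome, normalize_identifiers
from .survival import ElispotSeries

HTSEQ_SPECIAL = ("__no_feature", "__ambiguous", "__too_low_aQual",
                 "__not_aligned", "__alignment_not_unique")


def write_counts(study: CountStudy, counts_path, annotation_path) -> None:
    study.counts.to_csv(counts_path, sep="\t", index_label="gene")
    study.annotation.to_csv(annotation_path, sep="\t", index_label="sample")


def read_counts(counts_path, annotation_path) -> CountStudy:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
    annotation.index = annotation.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountStudy(counts.astype(int), annotation)


def read_htseq_dir(directory, annotation_path) -> CountStudy:
    """Assemble a count study from per-sample two-column HTSeq-count files.

    Each ``<sample>.txt``/``.tsv`` file holds (gene, count) rows; the
    trailing ``__*`` summary rows HTSeq emits are dropped.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix in {".txt", ".tsv"})
    if not files:
        raise ValueError(f"no HTSeq-count files in {directory}")
    cols = {}
    for p in files:
        s = pd.read_csv(p, sep="\t", header=None, names=["gene", "count"], index_col=0)
        s = s[~s.index.isin(HTSEQ_SPECIAL)]
        cols[p.stem] = s["count"]
    counts = pd.DataFrame(cols).fillna(0).astype(int)
    annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
    annotation.index = annotation.index.astype(str)
    return CountStudy(counts[list(annotation.index)], annotation)


def write_fraction(fraction: FractionProteome, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\n")
        for p in sorted(fraction.proteins):
            fh.write(p + "\n")


def read_fraction(path, fraction_id: str, activity: str,
                  mapping=None) -> FractionProteome:
    ids = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            cell = line.strip().split(",")[0]
            if not cell or (i == 0 and cell.lower() in {"protein", "id", "identifier"}):
                continue
            ids.append(cell)
    return FractionProteome(fraction_id, activity, normalize_identifiers(ids, mapping))


def write_psm_table(psms: pd.DataFrame, path) -> None:
    cols = [c for c in ("peptide", "protein", "length", "score", "is_decoy") if c in psms]
    psms[cols].to_csv(path, sep="\t", index=False)


def read_psm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def write_network(network: PPINetwork, path) -> None:
    network.edge_table().to_csv(path, sep="\t", index=False, header=False,
                                float_format="%.6f")


def write_elispot(series_list: list[ElispotSeries], path) -> None:
    rows = []
    for s in series_list:
        for _, r in s.observations.iterrows():
            rows.append({"condition": s.condition, "day": int(r["day"]),
                         "well": int(r["well"]), "spots": int(r["spots"])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_elispot(path) -> list[ElispotSeries]:
    df = pd.read_csv(path)
    return [
        ElispotSeries(str(cond), sub[["day", "well", "spots"]].reset_index(drop=True))
        for cond, sub in df.groupby("condition", sort=True)
    ]


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
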