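"""Readers and writers for the plain-text formats the pipeline exchanges.

Cohort CSV, counts TSV/MTX with replicate and group maps, GMT gene sets,
RNK ranked lists (single files or a per-drug/per-cell-line library layout)
and long-format plate CSVs.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .de import CountMatrix
from .drugsim import DrugSignature
from .enrich import GeneSet
from .plates import PlateAssay
from .stratify import FlareEvent, HCMeasure, PatientRecord

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_gmt",
    "read_gmt",
    "write_rnk",
    "read_rnk",
    "write_drug_library",
    "read_drug_library",
    "write_plates_csv",
    "read_plates_csv",
]


# --- cohort ---------------------------------------------------------------


def _fmt_measures(measures) -> str:
    return ";".join(
        f"{m.age_months!r}:{m.percentile!r}:{int(m.documented_by_physician)}"
        for m in measures
    )


def _fmt_events(events) -> str:
    return ";".join(f"{e.trigger}:{int(e.worsening)}" for e in events)


def write_cohort_csv(records: list[PatientRecord], path) -> None:
    rows = [
        {
            "id": r.id,
            "asd_diagnosis": int(r.asd_diagnosis),
            "hc_measures": _fmt_measures(r.hc_measures),
            "flare_assessable": int(r.flare_assessable),
            "flare_events": _fmt_events(r.flare_events),
            "genetic_screen": r.genetic_screen,
            "funnel_stage": r.funnel_stage or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        measures = []
        if row["hc_measures"]:
            for tok in row["hc_measures"].split(";"):
                age, pct, doc = tok.split(":")
                measures.append(HCMeasure(float(age), float(pct), bool(int(doc))))
        events = []
        if row["flare_events"]:
            for tok in row["flare_events"].split(";"):
                trig, wors = tok.rsplit(":", 1)
                events.append(FlareEvent(trig, bool(int(wors))))
        records.append(
            PatientRecord(
                id=row["id"],
                asd_diagnosis=bool(int(row["asd_diagnosis"])),
                hc_measures=measures,
                flare_assessable=bool(int(row["flare_assessable"])),
                flare_events=events,
                genetic_screen=row["genetic_screen"],
                funnel_stage=row["funnel_stage"] or None,
            )
        )
    return records


# --- counts ---------------------------------------------------------------


def write_counts_tsv(cm: CountMatrix, out_dir) -> None:
    """counts.tsv + replicate_map.tsv + subject_groups.tsv in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm.counts.to_csv(out / "counts.tsv", sep="\t")
    cm.replicate_map.rename("subject").rename_axis("sample").to_csv(
        out / "replicate_map.tsv", sep="\t"
    )
    cm.subject_group.rename("group").rename_axis("subject").to_csv(
        out / "subject_groups.tsv", sep="\t"
    )


def read_counts_tsv(in_dir) -> CountMatrix:
    ind = Path(in_dir)
    counts = pd.read_csv(ind / "counts.tsv", sep="\t", index_col=0)
    rep = pd.read_csv(ind / "replicate_map.tsv", sep="\t", index_col=0)["subject"]
    grp = pd.read_csv(ind / "subject_groups.tsv", sep="\t", index_col=0)["group"]
    return CountMatrix(counts=counts, replicate_map=rep, subject_group=grp)


def write_counts_mtx(cm: CountMatrix, out_dir) -> None:
    """MatrixMarket triple: matrix.mtx + genes.tsv + samples.tsv (+ maps)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(os.fspath(out / "matrix.mtx"), sparse.csr_matrix(cm.counts.to_numpy()))
    pd.Series(cm.counts.index).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(cm.counts.columns).to_csv(
        out / "samples.tsv", sep="\t", index=False, header=False
    )
    cm.replicate_map.rename("subject").rename_axis("sample").to_csv(
        out / "replicate_map.tsv", sep="\t"
    )
    cm.subject_group.rename("group").rename_axis("subject").to_csv(
        out / "subject_groups.tsv", sep="\t"
    )


def read_counts_mtx(in_dir) -> CountMatrix:
    ind = Path(in_dir)
    mat = sparse.csr_matrix(spio.mmread(os.fspath(ind / "matrix.mtx"))).toarray()
    genes = pd.read_csv(ind / "genes.tsv", sep="\t", header=None)[0]
    samples = pd.read_csv(ind / "samples.tsv", sep="\t", header=None)[0]
    counts = pd.DataFrame(mat.astype(np.int64), index=genes, columns=samples)
    rep = pd.read_csv(ind / "replicate_map.tsv", sep="\t", index_col=0)["subject"]
    grp = pd.read_csv(ind / "subject_groups.tsv", sep="\t", index_col=0)["group"]
    return CountMatrix(counts=counts, replicate_map=rep, subject_group=grp)


# --- gene sets and rankings ----------------------------------------------


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.note or 'na'}\t{members}\n")


def read_gmt(path) -> dict[str, GeneSet]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, note, *members = parts
            out[name] = GeneSet(name=name, members=frozenset(members), note=note)
    return out


def write_rnk(ranking, path, scores=None) -> None:
    """RNK file (gene<TAB>score, best first). Without explicit scores, a
    descending rank-based score is written so the order round-trips."""
    ranking = list(ranking)
    if scores is None:
        scores = np.arange(len(ranking), 0, -1, dtype=float)
    with open(path, "w") as fh:
        for g, s in zip(ranking, scores):
            fh.write(f"{g}\t{s:g}\n")


def read_rnk(path) -> list:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    return list(df.sort_values("score", ascending=False, kind="mergesort")["gene"])


def write_drug_library(signatures: list[DrugSignature], out_dir) -> None:
    """One RNK file per drug per cell line: ``<drug>/<cell_line>.rnk``."""
    out = Path(out_dir)
    for sig in signatures:
        d = out / sig.name
        d.mkdir(parents=True, exist_ok=True)
        for cl, ranking in sig.rankings.items():
            write_rnk(ranking, d / f"{cl}.rnk")


def read_drug_library(in_dir) -> list[DrugSignature]:
    ind = Path(in_dir)
    sigs = []
    for drug_dir in sorted(p for p in ind.iterdir() if p.is_dir()):
        rankings = {
            f.stem: read_rnk(f) for f in sorted(drug_dir.glob("*.rnk"))
        }
        if rankings:
            sigs.append(DrugSignature(name=drug_dir.name, rankings=rankings))
    return sigs


# --- plates ---------------------------------------------------------------


def write_plates_csv(assays: list[PlateAssay], path) -> None:
    rows = []
    for a in assays:
        for well, (comp, a590, a750) in a.wells.items():
            rows.append(
                {
                    "plate": a.plate_id,
                    "well": well,
                    "compound": comp,
                    "a590": a590,
                    "a750": a750,
                    "cell_line": a.cell_line_id,
                    "group": a.group,
                    "treatment": a.treatment,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plates_csv(path) -> list[PlateAssay]:
    df = pd.read_csv(path, keep_default_na=False)
    assays = []
    for (plate, cl, group, treat), sub in df.groupby(
        ["plate", "cell_line", "group", "treatment"], sort=False
    ):
        wells = {
            row.well: (row.compound, float(row.a590), float(row.a750))
            for row in sub.itertuples()
        }
        assays.append(
            PlateAssay(
                plate_id=plate,
                wells=wells,
                cell_line_id=cl,
                group=group,
                treatment=treat,
            )
        )
    return assays
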