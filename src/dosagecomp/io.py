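"""Readers and writers for the pipeline's file formats.

GFF3 (1-based inclusive coordinates, converted to the package's internal
0-based half-open convention on read), bedGraph depth tracks (0-based
half-open), and tab-separated tables for counts, sample sheets,
gametologue pairs and analysis reports. Report tables carry a commented
``# key: value`` metadata header block so every run is self-describing
while staying spreadsheet- and diff-friendly.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "write_gff3", "read_gff3",
    "write_bedgraph", "read_bedgraph",
    "write_counts", "read_counts",
    "write_samples", "read_samples",
    "write_pairs", "read_pairs",
    "write_report_table", "read_report_table",
]

VALID_GROUPS = {"XXf", "XYm", "XXm"}
_GROUP_OF = {("XX", "female"): "XXf", ("XY", "male"): "XYm",
             ("XX", "male"): "XXm"}


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: pd.DataFrame, features: pd.DataFrame, layout,
               path) -> None:
    """Write the annotation with layout truth embedded as pragmas.

    Coordinates are converted from internal 0-based half-open to GFF3
    1-based inclusive. Region class, gametologue partner and the silent
    flag travel in the gene attributes; scaffold lengths, the X/Y
    scaffold identities and the true PAR interval (recorded 0-based
    half-open) travel in header pragmas, so a written fixture set
    round-trips without a sidecar file.
    """
    lines = ["##gff-version 3"]
    for scaf, length in layout.scaffold_lengths.items():
        lines.append(f"##sequence-region {scaf} 1 {length}")
    lines.append(f"#!x-scaffold {layout.x_scaffold}")
    lines.append(f"#!y-scaffold {layout.y_scaffold}")
    lines.append(f"#!par-interval {layout.x_scaffold} "
                 f"{layout.par_start} {layout.par_end}")
    feat_by_gene = {g: df for g, df in features.groupby("gene_id")}
    for gid, row in genes.iterrows():
        attrs = [f"ID={gid}", f"region={row['region']}"]
        if row.get("partner", ""):
            attrs.append(f"partner={row['partner']}")
        if bool(row.get("silent", False)):
            attrs.append("silent=true")
        lines.append("\t".join([
            row["scaffold"], "dosagecomp", "gene",
            str(int(row["start"]) + 1), str(int(row["end"])),
            ".", "+", ".", ";".join(attrs),
        ]))
        for _, f in feat_by_gene.get(gid, pd.DataFrame()).iterrows():
            lines.append("\t".join([
                row["scaffold"], "dosagecomp", f["feature"],
                str(int(f["start"]) + 1), str(int(f["end"])),
                ".", "+", ".", f"Parent={gid}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path):
    """Read an annotation written by :func:`write_gff3`.

    Returns ``(genes, features, layout)`` with internal 0-based
    half-open coordinates. Layout pragmas are optional: a plain GFF3
    yields ``layout=None`` and empty region/partner columns.
    """
    from .simulate import GenomeLayout

    scaffold_lengths: dict[str, int] = {}
    x_scaf = y_scaf = None
    par = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line.strip().split()
            if line.startswith("##sequence-region"):
                scaffold_lengths[parts[1]] = int(parts[3])
            elif line.startswith("#!x-scaffold"):
                x_scaf = parts[1]
            elif line.startswith("#!y-scaffold"):
                y_scaf = parts[1]
            elif line.startswith("#!par-interval"):
                par = (int(parts[2]), int(parts[3]))

    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    gene_rows, feat_rows = [], []
    for g in db.features_of_type("gene"):
        gene_rows.append({
            "gene_id": g.id,
            "scaffold": g.seqid,
            "start": g.start - 1,
            "end": g.end,
            "region": g.attributes.get("region", [""])[0],
            "partner": g.attributes.get("partner", [""])[0],
            "silent": g.attributes.get("silent", ["false"])[0] == "true",
        })
    for ftype in ("CDS", "five_prime_utr", "three_prime_utr"):
        for f in db.features_of_type(ftype):
            feat_rows.append({
                "gene_id": f.attributes.get("Parent", [f.id])[0],
                "feature": ftype,
                "start": f.start - 1,
                "end": f.end,
            })
    genes = pd.DataFrame(gene_rows).set_index("gene_id")
    features = pd.DataFrame(feat_rows).sort_values(
        ["gene_id", "start"], kind="mergesort").reset_index(drop=True)
    from .expression import gene_lengths
    genes["length"] = gene_lengths(features).reindex(genes.index)

    layout = None
    if scaffold_lengths and x_scaf and y_scaf and par:
        autosomes = tuple(s for s in scaffold_lengths
                          if s not in (x_scaf, y_scaf))
        layout = GenomeLayout(scaffold_lengths=scaffold_lengths,
                              autosomes=autosomes, x_scaffold=x_scaf,
                              y_scaffold=y_scaf, par_start=par[0],
                              par_end=par[1])
    return genes, features, layout


# ------------------------------------------------------------ bedGraph

def write_bedgraph(tracks: dict[str, pd.DataFrame], path) -> None:
    """Write depth tracks as a single bedGraph (0-based half-open)."""
    frames = [t[["scaffold", "start", "end", "depth"]] for t in tracks.values()]
    pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> dict[str, pd.DataFrame]:
    """Read a bedGraph into one track per scaffold, validating the grid."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["scaffold", "start", "end", "depth"])
    # tolerate a UCSC "track ..." header line
    df = df[~df["scaffold"].astype(str).str.startswith("track")]
    df = df.astype({"start": int, "end": int, "depth": float})
    tracks = {}
    df["_line"] = np.arange(1, len(df) + 1)
    for scaf, sub in df.groupby("scaffold", sort=False):
        sub = sub.reset_index(drop=True)
        bad = np.flatnonzero(sub["end"].to_numpy()[:-1]
                             > sub["start"].to_numpy()[1:])
        if len(bad):
            line = int(sub["_line"].iloc[bad[0] + 1])
            raise ValueError(
                f"overlapping or unsorted windows in {path} at line {line}")
        if (sub["depth"] < 0).any():
            line = int(sub.loc[sub["depth"] < 0, "_line"].iloc[0])
            raise ValueError(f"negative depth in {path} at line {line}")
        tracks[scaf] = sub[["scaffold", "start", "end", "depth"]]
    return tracks


# ----------------------------------------------------------------- TSV

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    if counts.isna().any().any():
        raise ValueError(f"missing cells in count matrix {path}")
    if (counts < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    return counts


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    required = {"sample", "genotype", "phenotype", "group", "tissue"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    for _, row in samples.iterrows():
        expected = _GROUP_OF.get((row["genotype"], row["phenotype"]))
        if expected is None:
            raise ValueError(
                f"invalid genotype/phenotype combination for sample "
                f"{row['sample']}: {row['genotype']}/{row['phenotype']}")
        if row["group"] != expected:
            raise ValueError(
                f"group {row['group']} inconsistent with "
                f"{row['genotype']}/{row['phenotype']} for {row['sample']}")
    return samples


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[["x_gene", "y_gene"]].to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t")
    if not {"x_gene", "y_gene"} <= set(pairs.columns):
        raise ValueError(f"pairs table {path} needs x_gene and y_gene columns")
    return pairs


# -------------------------------------------------------------- reports

def write_report_table(df: pd.DataFrame, path, metadata: dict) -> None:
    """TSV with a commented key/value metadata header block."""
    with open(path, "w") as fh:
        for k, v in metadata.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report_table(path):
    """Read a report table; returns ``(df, metadata)``."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            k, _, v = line[1:].strip().partition(": ")
            meta[k] = v
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    return df, meta
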