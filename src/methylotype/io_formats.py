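"""Readers and writers for the tabular formats the pipeline consumes.

All genomic coordinates are held 0-based half-open internally (BED
convention).  GFF3 input (1-based, inclusive) is converted on read.

Formats handled here:

* sample sheet / survival / CCF / clonotype tables — plain TSV
* per-CpG modification calls — bedMethyl-like TSV with per-site depth
  and separate 5mC / 5hmC counts ("6-base" sequencing output)
* gene models — BED12/BED6 or GFF3
* somatic copy-number segments — SEG-style TSV
* gene sets — GMT, with optional ``key=value`` attributes in the
  description field (used for upstream-regulator activation scores)
* gene × sample matrices — TSV with ``NA`` for missing
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIMEPOINTS = ("baseline", "restaging", "progression")
SOURCES = ("plasma", "buffycoat")

#: timepoint → timepoint class; baseline is its own class, treated
#: (restaging/progression) samples share the "TR" background class.
TIMEPOINT_CLASS = {"baseline": "BL", "restaging": "TR", "progression": "TR"}

#: normal (non-tumor) copy number per chromosome; all-male cohort, so a
#: single X and a single Y.  Override via the ``cn_normal_map`` arguments.
DEFAULT_CN_NORMAL = {"chrX": 1, "chrY": 1, "X": 1, "Y": 1}


class FormatError(ValueError):
    """Raised when an input file cannot be parsed or fails validation."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# sample sheet and survival
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet and derive the timepoint class.

    Required columns: sample_id, case_id, timepoint, source, purity.
    Purity is the ctDNA fraction p_s; buffy-coat rows carry purity 0.
    Returns a DataFrame indexed by sample_id with a derived
    ``timepoint_class`` column (BL for baseline, TR otherwise).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "case_id": str})
    _require_columns(df, ["sample_id", "case_id", "timepoint", "source", "purity"], path)
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicated sample_id(s) {dups}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise FormatError(f"{path}: unknown timepoint(s) {sorted(bad_tp)}")
    bad_src = set(df["source"]) - set(SOURCES)
    if bad_src:
        raise FormatError(f"{path}: unknown source(s) {sorted(bad_src)}")
    purity = pd.to_numeric(df["purity"], errors="coerce")
    if purity.isna().any() or (purity < 0).any() or (purity > 1).any():
        raise FormatError(f"{path}: purity must be a fraction in [0, 1]")
    df["purity"] = purity
    df["timepoint_class"] = df["timepoint"].map(TIMEPOINT_CLASS)
    return df.set_index("sample_id", drop=False)


def write_sample_sheet(meta: pd.DataFrame, path) -> None:
    cols = ["sample_id", "case_id", "timepoint", "source", "purity"]
    meta[cols].to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    """Read the per-case survival table (rPFS / OS endpoints)."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str})
    _require_columns(
        df, ["case_id", "rpfs_months", "rpfs_event", "os_months", "os_event"], path
    )
    if df["case_id"].duplicated().any():
        raise FormatError(f"{path}: one record per case required")
    for col in ("rpfs_months", "os_months"):
        if (df[col] < 0).any():
            raise FormatError(f"{path}: {col} must be nonnegative")
    for col in ("rpfs_event", "os_event"):
        df[col] = df[col].astype(int).astype(bool)
    return df.set_index("case_id", drop=False)


def write_survival(surv: pd.DataFrame, path) -> None:
    out = surv[["case_id", "rpfs_months", "rpfs_event", "os_months", "os_event"]].copy()
    out["rpfs_event"] = out["rpfs_event"].astype(int)
    out["os_event"] = out["os_event"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

_STRANDS = {"+": "+", "-": "-", "−": "-"}  # accept unicode minus


@dataclass(frozen=True)
class GeneModel:
    """A gene locus in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise FormatError(f"gene {self.gene_id}: start must be < end")

    @property
    def tss(self) -> int:
        """Transcription start site: start on +, end−1 on −."""
        return self.start if self.strand == "+" else self.end - 1


def read_gene_models(path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED (6+ columns) or GFF3.

    ``fmt`` is inferred from the extension when omitted (.bed → BED,
    .gff/.gff3 → GFF3).  GFF3 coordinates (1-based inclusive) are
    converted to 0-based half-open.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "gff3" if ext in (".gff", ".gff3") else "bed"
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if fmt == "bed":
                    if len(fields) < 6:
                        raise FormatError("need ≥6 BED columns")
                    chrom, start, end, name, _, strand = fields[:6]
                    genes.append(
                        GeneModel(name, chrom, _parse_strand(strand), int(start), int(end))
                    )
                else:
                    if len(fields) < 9:
                        raise FormatError("need 9 GFF3 columns")
                    if fields[2] != "gene":
                        continue
                    chrom, start, end, strand = fields[0], fields[3], fields[4], fields[6]
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    name = attrs.get("ID", attrs.get("gene_id", f"gene{lineno}"))
                    genes.append(
                        GeneModel(name, chrom, _parse_strand(strand), int(start) - 1, int(end))
                    )
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_strand(symbol: str) -> str:
    try:
        return _STRANDS[symbol]
    except KeyError:
        raise FormatError(f"unknown strand symbol {symbol!r}")


def write_gene_models_bed(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# per-CpG modification calls
# ---------------------------------------------------------------------------

def read_cpg_calls(path, min_site_depth: int = 3) -> pd.DataFrame:
    """Read a per-CpG 5mC/5hmC call table and apply the site-depth filter.

    Expects TSV columns chrom, pos, depth, n_5mC, n_5hmC (pos 0-based).
    Sites with depth below ``min_site_depth`` are dropped; the count
    invariant n_5mC + n_5hmC ≤ depth is enforced.
    """
    if min_site_depth < 0:
        raise ValueError("min_site_depth must be ≥ 0")
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "pos", "depth", "n_5mC", "n_5hmC"], path)
    for col in ("pos", "depth", "n_5mC", "n_5hmC"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: malformed numeric value in column {col}, line {line}")
        df[col] = vals.astype(np.int64)
    if ((df[["pos", "depth", "n_5mC", "n_5hmC"]] < 0).any()).any():
        raise FormatError(f"{path}: negative counts/positions")
    over = df["n_5mC"] + df["n_5hmC"] > df["depth"]
    if over.any():
        line = int(over.index[over][0]) + 2
        raise FormatError(f"{path}: n_5mC + n_5hmC > depth at line {line}")
    if df.duplicated(["chrom", "pos"]).any():
        raise FormatError(f"{path}: duplicated (chrom, pos)")
    return df[df["depth"] >= min_site_depth].reset_index(drop=True)


def write_cpg_calls(calls: pd.DataFrame, path) -> None:
    calls[["chrom", "pos", "depth", "n_5mC", "n_5hmC"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def read_segments(path) -> pd.DataFrame:
    """Read a SEG-style table of somatic copy-number segments.

    Columns chrom, start, end, cn_tumor; segments must be non-overlapping
    within each chromosome.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "start", "end", "cn_tumor"], path)
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: segment start must be < end")
    if (df["cn_tumor"] < 0).any():
        raise FormatError(f"{path}: cn_tumor must be ≥ 0")
    for chrom, sub in df.groupby("chrom"):
        s = sub.sort_values("start")
        if (s["start"].values[1:] < s["end"].values[:-1]).any():
            raise FormatError(f"{path}: overlapping segments on {chrom}")
    return df.reset_index(drop=True)


def write_segments(segments: pd.DataFrame, path) -> None:
    segments[["chrom", "start", "end", "cn_tumor"]].to_csv(path, sep="\t", index=False)


def assign_gene_copy_number(segments: pd.DataFrame, genes: list[GeneModel]) -> pd.Series:
    """Assign each gene the copy number of its largest-overlap segment.

    Overlap is measured in base pairs against the gene body.  Ties go to
    the lower-coordinate segment; genes with no overlapping segment are
    missing (NaN).  Invariant to the input ordering of segments.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        str(chrom): sub.sort_values("start").reset_index(drop=True)
        for chrom, sub in segments.groupby("chrom")
    }
    out = {}
    for g in genes:
        sub = by_chrom.get(g.chrom)
        if sub is None:
            out[g.gene_id] = np.nan
            continue
        ov = np.minimum(sub["end"].values, g.end) - np.maximum(sub["start"].values, g.start)
        ov = np.clip(ov, 0, None)
        if ov.max(initial=0) <= 0:
            out[g.gene_id] = np.nan
        else:
            # argmax on the start-sorted frame breaks ties toward the
            # lower-coordinate segment
            out[g.gene_id] = float(sub["cn_tumor"].values[int(np.argmax(ov))])
    return pd.Series(out, name="cn_tumor")


def normal_copy_number(chrom: str, cn_normal_map: dict | None = None) -> int:
    """Normal-tissue copy number for a chromosome (2 autosomes, 1 X/Y)."""
    table = DEFAULT_CN_NORMAL if cn_normal_map is None else cn_normal_map
    return int(table.get(chrom, 2))


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set attributes.

    Attributes (e.g. upstream-regulator ``activation`` Z and overlap
    ``p``) are parsed from ``key=value`` pairs in the GMT description
    field when present.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    attrs: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def filtered(self, min_activation: float, max_p: float) -> "GeneSetCollection":
        """Subset to sets with |activation| above and p below thresholds."""
        keep = {}
        attrs = {}
        for name, genes in self.sets.items():
            a = self.attrs.get(name, {})
            if "activation" not in a or "p" not in a:
                continue
            if abs(a["activation"]) > min_activation and a["p"] < max_p:
                keep[name] = genes
                attrs[name] = a
        return GeneSetCollection(keep, attrs)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file; duplicate genes within a set are dropped."""
    sets: dict[str, list[str]] = {}
    attrs: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs ≥3 fields (empty set?)")
            name, desc = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}:{lineno}: set {name} is empty")
            sets[name] = genes
            a = {}
            for kv in desc.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    try:
                        a[k.strip()] = float(v)
                    except ValueError:
                        a[k.strip()] = v
            if a:
                attrs[name] = a
    return GeneSetCollection(sets, attrs)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            a = collection.attrs.get(name, {})
            desc = ";".join(f"{k}={v}" for k, v in a.items()) or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# CCF / clonotype tables, matrices
# ---------------------------------------------------------------------------

def read_ccf_table(path) -> pd.DataFrame:
    """Per-case, per-clone, per-timepoint cancer cell fractions."""
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "clone_id": str})
    _require_columns(df, ["case_id", "clone_id", "timepoint", "ccf"], path)
    if ((df["ccf"] < 0) | (df["ccf"] > 1)).any():
        raise FormatError(f"{path}: ccf must be in [0, 1]")
    if df.duplicated(["case_id", "clone_id", "timepoint"]).any():
        raise FormatError(f"{path}: (case, clone, timepoint) must be unique")
    return df


def write_ccf_table(ccf: pd.DataFrame, path) -> None:
    ccf[["case_id", "clone_id", "timepoint", "ccf"]].to_csv(path, sep="\t", index=False)


def read_clonotype_table(path) -> pd.DataFrame:
    """Per-sample clonotype counts (e.g. TRA/TRB CDR3 repertoires)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "clonotype_id": str})
    _require_columns(df, ["sample_id", "locus", "clonotype_id", "count"], path)
    if (df["count"] <= 0).any():
        raise FormatError(f"{path}: clonotype counts must be positive")
    return df


def write_clonotype_table(clonotypes: pd.DataFrame, path) -> None:
    clonotypes[["sample_id", "locus", "clonotype_id", "count"]].to_csv(
        path, sep="\t", index=False
    )


def read_gene_matrix(path) -> pd.DataFrame:
    """Gene × sample TSV matrix with ``NA`` for missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicated gene or sample labels")
    return df


def write_gene_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="gene_id")


def read_rna_counts(path) -> pd.DataFrame:
    counts = read_gene_matrix(path)
    if (counts.fillna(0) < 0).any().any():
        raise FormatError(f"{path}: RNA counts must be ≥ 0")
    return counts


# ---------------------------------------------------------------------------
# manifest validation
# ---------------------------------------------------------------------------

_READERS = {
    "sample_sheet": read_sample_sheet,
    "survival": read_survival,
    "gene_models": read_gene_models,
    "ccf": read_ccf_table,
    "clonotypes": read_clonotype_table,
    "rna_counts": read_rna_counts,
    "gmt": read_gmt,
    "segments": read_segments,
    "cpg_calls": read_cpg_calls,
    "matrix": read_gene_matrix,
}


def validate_directory(directory) -> dict:
    """Validate every input listed in ``MANIFEST.json`` under a directory.

    Returns a manifest dict mapping each entry to its parsed size; raises
    FormatError on the first invalid file.
    """
    manifest_path = os.path.join(directory, "MANIFEST.json")
    if not os.path.exists(manifest_path):
        raise FormatError(f"{directory}: no MANIFEST.json found")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    report = {}
    for entry in manifest.get("files", []):
        kind, rel = entry["kind"], entry["path"]
        reader = _READERS.get(kind)
        if reader is None:
            report[rel] = {"kind": kind, "status": "skipped (unknown kind)"}
            continue
        obj = reader(os.path.join(directory, rel))
        n = len(obj)
        report[rel] = {"kind": kind, "status": "ok", "n_records": n}
    return report
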