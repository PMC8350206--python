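"""Readers, writers and genomic-context annotation for methylation-array data.

Containers
----------
A cohort is held as a :class:`MethylationDataset`: a probe x sample matrix of
methylation beta values (fraction methylated, in [0, 1]) together with its
sample sheet.  Probe genomic context lives in a probe-annotation
:class:`pandas.DataFrame` with one row per probe (columns listed in
:data:`ANNOTATION_COLUMNS`).

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open.  BED files are ingested and
emitted untouched.  Probe positions in annotation TSVs follow the Illumina
manifest convention (1-based) and are converted on ingest and back on export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SampleRecord",
    "MethylationDataset",
    "Blacklist",
    "GenomicTrack",
    "ANNOTATION_COLUMNS",
    "ISLAND_CONTEXTS",
    "read_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_beta_matrix",
    "apply_blacklist",
    "read_bed_track",
    "write_bed_track",
    "annotate_probes",
    "read_probe_annotation",
    "write_probe_annotation",
    "map_region_to_genes",
    "read_de_list",
    "write_de_list",
    "write_outputs",
]

ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")

#: canonical column order of a probe-annotation frame (probe_id is the index)
ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "island_context",
    "chromatin_state",
    "ctcf",
    "ezh2",
    "genes",
    "state_imputed",
]

# distance cut-offs (bp) from the nearest CpG island edge:
# 0 -> island, (0, 2 kb] -> shore, (2 kb, 4 kb] -> shelf, > 4 kb -> open sea
SHORE_BP = 2_000
SHELF_BP = 4_000

DEFAULT_STATE = "Quies"


@dataclass(frozen=True)
class SampleRecord:
    """One profiled muscle sample and its modelling covariates."""

    sample_id: str
    subject_id: str
    age: float
    sex: str | None = None
    bmi: float | None = None
    t2d: int | None = None
    batch: str | None = None
    time_point: str | None = None
    twin_pair: str | None = None

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError(f"sample {self.sample_id!r}: empty subject_id")
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: age must be positive, got {self.age}"
            )


@dataclass
class MethylationDataset:
    """One cohort: beta matrix (probe x sample) plus its sample sheet.

    ``beta`` is a DataFrame indexed by probe id with one column per sample;
    missing values are NaN.  Sample columns and ``samples`` records match
    one to one, in order.
    """

    dataset_id: str
    beta: pd.DataFrame
    samples: list[SampleRecord]
    array_label: str = "EPIC"

    def __post_init__(self) -> None:
        sheet_ids = [s.sample_id for s in self.samples]
        if list(self.beta.columns) != sheet_ids:
            raise ValueError(
                f"{self.dataset_id}: beta columns do not match sample sheet order"
            )
        if self.beta.index.has_duplicates:
            dup = self.beta.index[self.beta.index.duplicated()][0]
            raise ValueError(f"{self.dataset_id}: duplicate probe id {dup!r}")
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & np.isfinite(vals)):
            i, j = np.argwhere(bad & np.isfinite(vals))[0]
            raise ValueError(
                f"{self.dataset_id}: beta out of [0,1] at probe "
                f"{self.beta.index[i]!r}, sample {self.beta.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def sample_frame(self) -> pd.DataFrame:
        """Sample sheet as a DataFrame indexed by sample_id."""
        rows = [
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "t2d": s.t2d,
                "batch": s.batch,
                "time_point": s.time_point,
                "twin_pair": s.twin_pair,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("sample_id")

    def subset_samples(self, keep: Sequence[str]) -> "MethylationDataset":
        keep = list(keep)
        samples = [s for s in self.samples if s.sample_id in set(keep)]
        return replace(
            self,
            beta=self.beta.loc[:, [s.sample_id for s in samples]],
            samples=samples,
        )


@dataclass(frozen=True)
class Blacklist:
    """Cross-hybridizing (or otherwise untrusted) probes to drop on ingest."""

    probe_ids: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_file(cls, path: str | Path) -> "Blacklist":
        ids = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
        return cls(frozenset(ids))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample TSV of beta values.

    First column holds probe ids, remaining columns one sample each.  Missing
    cells stay NaN; any finite value outside [0, 1] or non-numeric cell is an
    error locating the offending cell.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            probe = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric value at probe {probe!r}, column {col!r}")
        oob = converted.notna() & ((converted < 0) | (converted > 1))
        if oob.any():
            probe = df.index[oob][0]
            raise ValueError(
                f"{path}: beta outside [0,1] at probe {probe!r}, column {col!r}"
            )
        out[col] = converted
    return out


def write_beta_matrix(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


_REQUIRED_SHEET_COLS = ("sample_id", "subject_id", "age")
_OPTIONAL_SHEET_COLS = ("sex", "bmi", "t2d", "batch", "time_point", "twin_pair")


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a sample sheet CSV into :class:`SampleRecord` objects.

    ``sample_id``, ``subject_id`` and ``age`` are required; covariate columns
    are optional and missing entries are kept missing, never imputed.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    for col in _REQUIRED_SHEET_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _OPTIONAL_SHEET_COLS:
            if col in df.columns and pd.notna(row[col]):
                val = row[col]
                if col == "bmi":
                    val = float(val)
                elif col == "t2d":
                    val = int(val)
                else:
                    val = str(val)
                kwargs[col] = val
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                **kwargs,
            )
        )
    return records


def write_sample_sheet(samples: Sequence[SampleRecord], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "age": s.age,
                "sex": s.sex,
                "bmi": s.bmi,
                "t2d": s.t2d,
                "batch": s.batch,
                "time_point": s.time_point,
                "twin_pair": s.twin_pair,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def apply_blacklist(dataset: MethylationDataset, bl: Blacklist) -> MethylationDataset:
    """Drop blacklisted probes; order of the survivors is preserved."""
    keep = [p for p in dataset.beta.index if p not in bl.probe_ids]
    return replace(dataset, beta=dataset.beta.loc[keep])


# ---------------------------------------------------------------------------
# interval tracks
# ---------------------------------------------------------------------------


class GenomicTrack:
    """A labelled set of genomic intervals (0-based half-open) with point query."""

    def __init__(self, label: str):
        self.label = label
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, name: str | None = None) -> None:
        if start >= end:
            raise ValueError(f"{self.label}: start >= end ({chrom}:{start}-{end})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, name)

    def query_point(self, chrom: str, pos0: int) -> list[tuple[int, int, str | None]]:
        """Intervals containing 0-based position ``pos0``, sorted by start."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.at(pos0), key=lambda iv: (iv.begin, iv.end))
        return [(iv.begin, iv.end, iv.data) for iv in hits]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._trees

    def intervals(self, chrom: str) -> list[tuple[int, int, str | None]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree)

    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def read_bed_track(path: str | Path, label: str) -> GenomicTrack:
    """Read a BED file (0-based half-open; optional 4th column = name)."""
    track = GenomicTrack(label)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            track.add(chrom, start, end, fields[3] if len(fields) > 3 else None)
    return track


def write_bed_track(track: GenomicTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, end, name in track.intervals(chrom):
                if name is None:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
                else:
                    fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------


def _island_context(dist_bp: float) -> str:
    if dist_bp <= 0:
        return "island"
    if dist_bp <= SHORE_BP:
        return "shore"
    if dist_bp <= SHELF_BP:
        return "shelf"
    return "open_sea"


def annotate_probes(
    probes: pd.DataFrame,
    islands: GenomicTrack,
    states: GenomicTrack,
    tf_sites: Mapping[str, GenomicTrack],
    gene_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Annotate probes with CpG-island context, chromatin state, TF binding and genes.

    Parameters
    ----------
    probes
        DataFrame indexed by probe id with columns ``chrom`` and ``pos``
        (0-based).  Probes with missing chrom/pos get missing context.
    islands, states
        CpG-island and chromatin-state tracks.
    tf_sites
        Mapping of flag name (e.g. ``ctcf``, ``ezh2``) to its binding track.
    gene_map
        probe id -> iterable of gene symbols (body/promoter/enhancer-linked).

    Island context is assigned from the distance to the nearest island edge:
    0 bp means inside an island, up to 2 kb is shore, 2-4 kb is shelf and
    beyond 4 kb is open sea, so contexts partition the probes.  When
    chromatin-state intervals overlap, the interval with the smallest start
    wins; probes on a chromosome absent from the state track fall back to the
    quiescent state and are flagged ``state_imputed``.
    """
    records = []
    # cache sorted island intervals per chromosome for distance queries
    island_edges: dict[str, np.ndarray] = {}
    for chrom in islands.chroms():
        ivs = islands.intervals(chrom)
        island_edges[chrom] = np.array([(s, e) for s, e, _ in ivs], dtype=float)

    for probe_id, row in probes.iterrows():
        chrom = row["chrom"]
        pos = row["pos"]
        if pd.isna(chrom) or pd.isna(pos):
            records.append(
                {
                    "probe_id": probe_id,
                    "chrom": None,
                    "pos": np.nan,
                    "island_context": None,
                    "chromatin_state": None,
                    "ctcf": 0,
                    "ezh2": 0,
                    "genes": tuple(sorted(gene_map.get(probe_id, ()))),
                    "state_imputed": True,
                }
            )
            continue
        pos = int(pos)
        edges = island_edges.get(chrom)
        if edges is None or len(edges) == 0:
            dist = np.inf
        else:
            # distance to nearest island: 0 if inside [start, end)
            inside = (edges[:, 0] <= pos) & (pos < edges[:, 1])
            if inside.any():
                dist = 0.0
            else:
                dist = float(
                    np.min(
                        np.minimum(
                            np.abs(edges[:, 0] - pos),
                            np.abs(pos - (edges[:, 1] - 1)),
                        )
                    )
                )
        state_hits = states.query_point(chrom, pos)
        if state_hits:
            state = state_hits[0][2] or DEFAULT_STATE
            imputed = False
        else:
            state = DEFAULT_STATE
            imputed = not states.has_chrom(chrom)
        flags = {
            name: int(bool(track.query_point(chrom, pos)))
            for name, track in tf_sites.items()
        }
        records.append(
            {
                "probe_id": probe_id,
                "chrom": chrom,
                "pos": pos,
                "island_context": _island_context(dist),
                "chromatin_state": state,
                "ctcf": flags.get("ctcf", 0),
                "ezh2": flags.get("ezh2", 0),
                "genes": tuple(sorted(gene_map.get(probe_id, ()))),
                "state_imputed": imputed,
            }
        )
    out = pd.DataFrame.from_records(records).set_index("probe_id")
    return out[ANNOTATION_COLUMNS]


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation TSV; positions are 1-based on disk."""
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    df["pos"] = df["pos"].astype("float") - 1  # to 0-based
    df["genes"] = [
        tuple(g.split(";")) if isinstance(g, str) and g else ()
        for g in df["genes"]
    ]
    df["state_imputed"] = df.get("state_imputed", False)
    if df["state_imputed"].dtype != bool:
        df["state_imputed"] = df["state_imputed"].astype(bool)
    return df[ANNOTATION_COLUMNS]


def write_probe_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    df = annotation.copy()
    df["pos"] = df["pos"] + 1  # back to 1-based manifest convention
    df["pos"] = df["pos"].astype("Int64")
    df["genes"] = [";".join(g) for g in df["genes"]]
    df.to_csv(path, sep="\t", index_label="probe_id")


def map_region_to_genes(
    chrom: str, start: int, end: int, annotation: pd.DataFrame
) -> set[str]:
    """Union of gene sets of probes inside a 0-based half-open region.

    Enhancer-linked genes carried by the probe annotation are included even
    when the region itself is intergenic.
    """
    sel = annotation[
        (annotation["chrom"] == chrom)
        & (annotation["pos"] >= start)
        & (annotation["pos"] < end)
    ]
    genes: set[str] = set()
    for g in sel["genes"]:
        genes.update(g)
    return genes


def read_de_list(path: str | Path) -> pd.DataFrame:
    """Read a two-column differential-expression list TSV: gene, direction (+1/-1)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df["direction"] = df["direction"].astype(int)
    return df.set_index("gene")


def write_de_list(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------


def write_outputs(
    out_dir: str | Path,
    dmps: pd.DataFrame | None = None,
    dmrs: pd.DataFrame | None = None,
    enrichments: Mapping[str, pd.DataFrame] | None = None,
    clock_model=None,
) -> dict[str, Path]:
    """Write pipeline results under ``out_dir``; returns the paths written.

    The DMR BED carries (chrom, start, end, name, score, strand) with
    score = -log10 of the Stouffer p and strand ".".
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    if dmps is not None:
        p = out_dir / "dmps.csv"
        dmps.to_csv(p, index_label="probe_id")
        written["dmps"] = p
    if dmrs is not None:
        p = out_dir / "dmrs.tsv"
        export = dmrs.copy()
        if "probe_ids" in export.columns:
            export["probe_ids"] = [";".join(v) for v in export["probe_ids"]]
        if "genes" in export.columns:
            export["genes"] = [";".join(sorted(v)) for v in export["genes"]]
        export.to_csv(p, sep="\t", index=False)
        written["dmrs"] = p
        bed = out_dir / "dmrs.bed"
        with open(bed, "w") as fh:
            for i, row in dmrs.iterrows():
                score = -np.log10(max(row["stouffer_p"], np.finfo(float).tiny))
                fh.write(
                    f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                    f"DMR_{i}\t{score:.4f}\t.\n"
                )
        written["dmrs_bed"] = bed
    for name, table in (enrichments or {}).items():
        p = out_dir / f"enrichment_{name}.tsv"
        table.to_csv(p, sep="\t")
        written[f"enrichment_{name}"] = p
    if clock_model is not None:
        p = out_dir / "clock_model.json"
        with open(p, "w") as fh:
            json.dump(clock_model.to_dict(), fh, indent=1)
        written["clock_model"] = p
    return written
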