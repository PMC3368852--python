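"""Domain types and readers/writers for every external format the pipeline touches.

The pipeline's in-memory currency is the :class:`DatasetBundle`: a set of named,
pre-aligned ITS2 sequence variants, a list of per-sample clone libraries (multisets
of variant labels with factor metadata), and optionally a diploid host genotype
table and environmental time series.

All on-disk formats are plain text: FASTA for sequences (Biopython), TSV for
counts, metadata, flags, genotypes and environment series. ``-`` is the only gap
symbol and alignment is an *input* — the pipeline never aligns sequences itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceVariant",
    "CloneLibrary",
    "GenotypeTable",
    "EnvSeries",
    "DatasetBundle",
    "load_variants",
    "write_variants",
    "load_libraries",
    "write_libraries",
    "load_genotypes",
    "load_env_series",
    "validate_bundle",
    "write_bundle",
    "load_bundle",
]

_VALID_SYMBOLS = set("ACGT-")


@dataclass(frozen=True)
class SequenceVariant:
    """A named ITS2 sequence variant from an aligned clone-library dataset.

    Labels follow the field convention of clade letter + closest published type
    + optional decimal (e.g. ``C31``, ``D1a.1``). ``published`` marks variants
    verified in earlier studies; ``pseudogene_flagged`` marks variants whose
    secondary-structure fold is aberrant (supplied as an input flag, never
    computed here).
    """

    label: str
    clade: str
    sequence: str
    published: bool = False
    pseudogene_flagged: bool = False

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("variant label must be non-empty")
        if not self.sequence:
            raise ValueError(f"variant {self.label!r}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - _VALID_SYMBOLS
        if bad:
            raise ValueError(
                f"variant {self.label!r}: invalid symbols {sorted(bad)} (alphabet is A,C,G,T,-)"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass
class CloneLibrary:
    """One sample's multiset of variant labels with counts plus factor metadata.

    ``life_stage`` is ``adult`` or ``egg``; ``morphology`` is ``branching``,
    ``plating`` or ``unknown``. Counts are strictly positive; zero-count labels
    are dropped at load time.
    """

    sample_id: str
    colony_id: str
    site: str
    year: int
    life_stage: str
    morphology: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.life_stage not in {"adult", "egg"}:
            raise ValueError(
                f"sample {self.sample_id!r}: life_stage must be 'adult' or 'egg', got {self.life_stage!r}"
            )
        for label, c in self.counts.items():
            if not isinstance(c, (int, np.integer)) or isinstance(c, bool) or c < 1:
                raise ValueError(
                    f"sample {self.sample_id!r}: count for {label!r} must be a positive integer, got {c!r}"
                )

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def labels(self) -> set[str]:
        return set(self.counts)

    def is_empty(self) -> bool:
        return not self.counts


@dataclass
class GenotypeTable:
    """Diploid genotypes for host individuals with a two-level grouping hierarchy.

    Each individual carries exactly two allele labels (phased input; phase
    inference is out of scope). ``groupings`` maps individual id to
    ``(group, sample)`` — e.g. morphology → collection sample. Allele distances
    come either from aligned allele sequences (Hamming) or from a precomputed
    matrix.
    """

    individuals: list[tuple[str, str, str]]  # (individual_id, allele_a, allele_b)
    groupings: dict[str, tuple[str, str]]
    allele_sequences: dict[str, str] | None = None
    allele_distances: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [i for i, _, _ in self.individuals]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate individual ids in genotype table")
        for ind in ids:
            if ind not in self.groupings:
                raise ValueError(f"individual {ind!r} has no grouping entry")

    @property
    def allele_labels(self) -> set[str]:
        out: set[str] = set()
        for _, a, b in self.individuals:
            out.update((a, b))
        return out


@dataclass
class EnvSeries:
    """One site's time series for one environmental variable."""

    site: str
    variable: str  # "temperature" (degC) or "light" (umol quanta m-2 s-1)
    timestamps: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"env series {self.site}/{self.variable}: non-finite values")
        if len(self.timestamps) != self.values.size:
            raise ValueError("timestamps and values length mismatch")


@dataclass
class DatasetBundle:
    """Everything one analysis run consumes, cross-referentially validated."""

    variants: dict[str, SequenceVariant]
    libraries: list[CloneLibrary]
    genotypes: GenotypeTable | None = None
    env: list[EnvSeries] = field(default_factory=list)

    def variant_set(self) -> list[SequenceVariant]:
        return list(self.variants.values())


# ---------------------------------------------------------------------------
# FASTA + flags


def _clade_from_label(label: str) -> str:
    return label[0].upper() if label else "?"


def load_variants(fasta_path, flags_path=None) -> dict[str, SequenceVariant]:
    """Load aligned variants from FASTA with an optional TSV flag sidecar.

    The flags TSV has columns ``label``, ``clade`` (optional), ``published``,
    ``pseudogene`` (0/1 or true/false). Missing flags default to unpublished,
    not pseudogene-flagged; missing clade defaults to the label's first letter.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    seen: set[str] = set()
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate label {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        offender = next(r for r in records if len(str(r.seq)) != len(str(records[0].seq)))
        raise ValueError(
            f"unequal aligned lengths in {fasta_path}: record {offender.id!r} "
            f"has length {len(str(offender.seq))}, expected {len(str(records[0].seq))}"
        )

    flags: dict[str, dict] = {}
    if flags_path is not None:
        ftab = pd.read_csv(flags_path, sep="\t", dtype=str).fillna("")
        if "label" not in ftab.columns:
            raise ValueError(f"flags file {flags_path} lacks a 'label' column")
        unknown = set(ftab["label"]) - set(seqs)
        if unknown:
            raise ValueError(f"flags file references labels absent from FASTA: {sorted(unknown)}")
        for _, row in ftab.iterrows():
            flags[row["label"]] = {
                "clade": row.get("clade", "") or _clade_from_label(row["label"]),
                "published": _parse_bool(row.get("published", "")),
                "pseudogene": _parse_bool(row.get("pseudogene", "")),
            }

    out: dict[str, SequenceVariant] = {}
    for label, seq in seqs.items():
        f = flags.get(label, {})
        out[label] = SequenceVariant(
            label=label,
            clade=f.get("clade", _clade_from_label(label)),
            sequence=seq,
            published=f.get("published", False),
            pseudogene_flagged=f.get("pseudogene", False),
        )
    return out


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in {"1", "true", "yes", "y"}


def write_variants(variants: Mapping[str, SequenceVariant], fasta_path, flags_path) -> None:
    records = [
        SeqRecord(Seq(v.sequence), id=v.label, description="") for v in variants.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "label": v.label,
            "clade": v.clade,
            "published": int(v.published),
            "pseudogene": int(v.pseudogene_flagged),
        }
        for v in variants.values()
    ]
    pd.DataFrame(rows).to_csv(flags_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clone-count tables

_FACTOR_COLUMNS = ["sample_id", "colony_id", "site", "year", "life_stage", "morphology"]


def load_libraries(counts_tsv, metadata_tsv) -> list[CloneLibrary]:
    """Load clone libraries from a counts table plus a metadata table.

    The counts table is auto-detected as either wide (rows = samples, columns =
    variant labels, first column ``sample_id``) or long (columns exactly
    ``sample_id``, ``variant``, ``count``). Zero cells are dropped; negative or
    non-integer counts and samples without metadata are hard errors.
    """
    counts = pd.read_csv(counts_tsv, sep="\t")
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype={"sample_id": str, "colony_id": str})
    missing_cols = [c for c in _FACTOR_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks columns {missing_cols}")
    meta = meta.set_index("sample_id")

    long_form = set(counts.columns) == {"sample_id", "variant", "count"}
    per_sample: dict[str, dict[str, int]] = {}
    if long_form:
        for _, row in counts.iterrows():
            sid = str(row["sample_id"])
            per_sample.setdefault(sid, {})
            c = row["count"]
            _check_count(c, sid, row["variant"])
            if int(c) > 0:
                per_sample[sid][str(row["variant"])] = int(c)
    else:
        if counts.columns[0] != "sample_id":
            raise ValueError("wide counts table must have 'sample_id' as its first column")
        for _, row in counts.iterrows():
            sid = str(row["sample_id"])
            per_sample[sid] = {}
            for label in counts.columns[1:]:
                c = row[label]
                if pd.isna(c):
                    continue
                _check_count(c, sid, label)
                if int(c) > 0:
                    per_sample[sid][str(label)] = int(c)

    libraries: list[CloneLibrary] = []
    for sid, cmap in per_sample.items():
        if sid not in meta.index:
            raise ValueError(f"sample {sid!r} present in counts but absent from metadata")
        if not cmap:
            raise ValueError(f"empty library for sample {sid!r}")
        m = meta.loc[sid]
        libraries.append(
            CloneLibrary(
                sample_id=sid,
                colony_id=str(m["colony_id"]),
                site=str(m["site"]),
                year=int(m["year"]),
                life_stage=str(m["life_stage"]),
                morphology=str(m["morphology"]),
                counts=cmap,
            )
        )
    return libraries


def _check_count(c, sid, label) -> None:
    try:
        cf = float(c)
    except (TypeError, ValueError):
        raise ValueError(f"sample {sid!r}: non-numeric count {c!r} for {label!r}") from None
    if cf < 0 or cf != int(cf):
        raise ValueError(f"sample {sid!r}: negative or non-integer count {c!r} for {label!r}")


def write_libraries(libraries: Sequence[CloneLibrary], counts_tsv, metadata_tsv) -> None:
    """Write libraries as a wide counts TSV plus a metadata TSV."""
    all_labels = sorted({l for lib in libraries for l in lib.counts})
    rows = []
    for lib in libraries:
        row: dict = {"sample_id": lib.sample_id}
        for label in all_labels:
            row[label] = lib.counts.get(label, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(counts_tsv, sep="\t", index=False)
    meta_rows = [
        {
            "sample_id": lib.sample_id,
            "colony_id": lib.colony_id,
            "site": lib.site,
            "year": lib.year,
            "life_stage": lib.life_stage,
            "morphology": lib.morphology,
        }
        for lib in libraries
    ]
    pd.DataFrame(meta_rows).to_csv(metadata_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotypes and environment


def load_genotypes(genotypes_tsv, allele_fasta=None, allele_dist_tsv=None) -> GenotypeTable:
    """Load a diploid genotype table.

    The TSV has columns ``individual_id``, ``group``, ``sample``, ``allele_a``,
    ``allele_b``. Allele distances come from an aligned allele FASTA or a square
    distance TSV (labels as header and first column).
    """
    tab = pd.read_csv(genotypes_tsv, sep="\t", dtype=str)
    required = {"individual_id", "group", "sample", "allele_a", "allele_b"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"genotype table lacks columns {sorted(missing)}")
    individuals = [
        (row["individual_id"], row["allele_a"], row["allele_b"]) for _, row in tab.iterrows()
    ]
    groupings = {
        row["individual_id"]: (row["group"], row["sample"]) for _, row in tab.iterrows()
    }
    allele_sequences = None
    allele_distances = None
    if allele_fasta is not None:
        recs = list(SeqIO.parse(str(allele_fasta), "fasta"))
        allele_sequences = {r.id: str(r.seq).upper() for r in recs}
    if allele_dist_tsv is not None:
        allele_distances = pd.read_csv(allele_dist_tsv, sep="\t", index_col=0)
    return GenotypeTable(
        individuals=individuals,
        groupings=groupings,
        allele_sequences=allele_sequences,
        allele_distances=allele_distances,
    )


def load_env_series(env_tsv) -> list[EnvSeries]:
    """Load environment series from a TSV with columns site, variable, timestamp, value."""
    tab = pd.read_csv(env_tsv, sep="\t")
    required = {"site", "variable", "timestamp", "value"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"environment table lacks columns {sorted(missing)}")
    out = []
    for (site, variable), grp in tab.groupby(["site", "variable"], sort=False):
        out.append(
            EnvSeries(
                site=str(site),
                variable=str(variable),
                timestamps=[str(t) for t in grp["timestamp"]],
                values=grp["value"].to_numpy(dtype=float),
            )
        )
    return out


def write_env_series(series: Sequence[EnvSeries], env_tsv) -> None:
    rows = []
    for s in series:
        for t, v in zip(s.timestamps, s.values):
            rows.append({"site": s.site, "variable": s.variable, "timestamp": t, "value": v})
    pd.DataFrame(rows).to_csv(env_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bundle validation and round-trip


def validate_bundle(bundle: DatasetBundle) -> list[str]:
    """Cross-referential integrity check. Returns a list of human-readable findings.

    An empty list means every library label resolves against the variant set,
    every genotype allele resolves against the allele sequences/distances, and
    factor combinations are well-formed. Findings are returned, not raised —
    the caller decides severity.
    """
    findings: list[str] = []
    known = set(bundle.variants)
    lengths = {len(v.sequence) for v in bundle.variants.values()}
    if len(lengths) > 1:
        findings.append(f"variant sequences have unequal aligned lengths: {sorted(lengths)}")
    seen_samples: set[str] = set()
    for lib in bundle.libraries:
        if lib.sample_id in seen_samples:
            findings.append(f"duplicate sample_id {lib.sample_id!r}")
        seen_samples.add(lib.sample_id)
        for label in lib.counts:
            if label not in known:
                findings.append(f"unknown variant {label} in sample {lib.sample_id}")
        if lib.is_empty():
            findings.append(f"empty library {lib.sample_id}")
    if bundle.genotypes is not None:
        g = bundle.genotypes
        have = set()
        if g.allele_sequences:
            have |= set(g.allele_sequences)
        if g.allele_distances is not None:
            have |= set(map(str, g.allele_distances.index))
        for ind, a, b in g.individuals:
            for allele in (a, b):
                if have and allele not in have:
                    findings.append(f"genotype allele {allele} of {ind} unresolvable")
    return findings


def write_bundle(bundle: DatasetBundle, outdir) -> None:
    """Write a bundle to a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_variants(bundle.variants, outdir / "variants.fasta", outdir / "variant_flags.tsv")
    write_libraries(bundle.libraries, outdir / "counts.tsv", outdir / "metadata.tsv")
    if bundle.env:
        write_env_series(bundle.env, outdir / "environment.tsv")
    if bundle.genotypes is not None:
        g = bundle.genotypes
        rows = [
            {
                "individual_id": ind,
                "group": g.groupings[ind][0],
                "sample": g.groupings[ind][1],
                "allele_a": a,
                "allele_b": b,
            }
            for ind, a, b in g.individuals
        ]
        pd.DataFrame(rows).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        if g.allele_sequences:
            recs = [
                SeqRecord(Seq(s), id=lab, description="")
                for lab, s in g.allele_sequences.items()
            ]
            SeqIO.write(recs, str(outdir / "alleles.fasta"), "fasta")


def load_bundle(indir) -> DatasetBundle:
    """Load a bundle previously written with :func:`write_bundle`."""
    indir = Path(indir)
    variants = load_variants(indir / "variants.fasta", indir / "variant_flags.tsv")
    libraries = load_libraries(indir / "counts.tsv", indir / "metadata.tsv")
    env: list[EnvSeries] = []
    if (indir / "environment.tsv").exists():
        env = load_env_series(indir / "environment.tsv")
    genotypes = None
    if (indir / "genotypes.tsv").exists():
        allele_fasta = indir / "alleles.fasta"
        genotypes = load_genotypes(
            indir / "genotypes.tsv",
            allele_fasta=allele_fasta if allele_fasta.exists() else None,
        )
    return DatasetBundle(variants=variants, libraries=libraries, genotypes=genotypes, env=env)
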