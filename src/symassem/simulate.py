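"""Synthetic dataset generator emulating ITS2 clone-library studies.

The generator produces complete :class:`~symassem.io.DatasetBundle` objects
with the statistical structure the analysis assumes: two deeply divergent
symbiont clades (C and D), a few dominant variants per clade, satellite
variants 1-3 edits from a recorded dominant, and per-sample clone libraries of
7-13 clones drawn Dirichlet-multinomially from site- and colony-dependent
community compositions. Egg libraries either mirror the parental composition
(``faithful``) or shift clade-D-rich parents toward clade C (``shifted``,
emulating preferential transmission).

Every stochastic choice is recorded in a truth record so oracle tests can
recompute edit counts, mixing weights and clade labels independently of the
pipeline under test. The same seed yields a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import CloneLibrary, DatasetBundle, EnvSeries, GenotypeTable, SequenceVariant
from .published_counts import (
    PSEUDOGENES,
    PUBLISHED,
    PUBLISHED_ROWS,
    all_labels,
    morphology_for,
    parse_counts,
)

__all__ = ["SimConfig", "make_variants", "simulate_bundle", "published_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated study where it states them: libraries of 7-13
    clones, satellites 1-3 edits from a dominant, two clades. The inter-clade
    divergence (0.25) and aligned length (320) are stand-ins the study does not
    pin down; they are documented as non-canonical in the methods note.
    """

    aligned_length: int = 320
    n_clade_dominants: int = 2          # dominants per clade
    n_satellites_per_dominant: int = 2
    variant_edit_range: tuple[int, int] = (1, 3)
    dominant_spacing: int = 3           # edits between successive dominants of a clade
    interclade_divergence: float = 0.25
    sites: tuple[str, ...] = ("BTN", "GL")
    years: tuple[int, ...] = (2007, 2008)
    site_morphology: Mapping[str, str] = field(
        default_factory=lambda: {"BTN": "branching", "GL": "plating", "PR": "unknown"}
    )
    n_colonies: int = 8                 # per site
    library_size_range: tuple[int, int] = (7, 13)
    egg_model: str = "faithful"         # faithful | shifted
    shifted_c_weight: float = 0.7       # mass moved to clade C in shifted eggs
    clade_d_sites: tuple[str, ...] = ("BTN",)  # sites with clade-D-rich adults
    dirichlet_concentration: float = 8.0
    pseudogene_injection: tuple[str, ...] = ()
    with_genotypes: bool = False
    with_env: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.variant_edit_range
        if not 1 <= lo <= hi:
            raise ValueError("variant_edit_range must satisfy 1 <= lo <= hi")
        lo, hi = self.library_size_range
        if not 1 <= lo <= hi:
            raise ValueError("library_size_range must satisfy 1 <= lo <= hi")
        if not 0 <= self.interclade_divergence <= 1:
            raise ValueError("interclade_divergence must be in [0, 1]")
        if self.egg_model not in {"faithful", "shifted"}:
            raise ValueError(f"unknown egg_model {self.egg_model!r}")
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")


def _mutate(rng: np.random.Generator, seq: np.ndarray, n_edits: int) -> tuple[np.ndarray, list[int]]:
    """Apply n_edits substitutions at distinct positions; returns (seq, positions)."""
    pos = rng.choice(len(seq), size=n_edits, replace=False)
    out = seq.copy()
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return out, sorted(int(p) for p in pos)


def make_variants(config: SimConfig, seed: int | None = None) -> tuple[dict[str, SequenceVariant], dict]:
    """Generate the variant set plus a truth record of every edit.

    The truth record maps each satellite label to its (dominant label, edit
    count, edited positions); ``truth["clade"]`` maps label -> clade.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    length = config.aligned_length
    anc_c = rng.choice(_BASES, size=length)
    n_div = int(round(config.interclade_divergence * length))
    anc_d, _ = _mutate(rng, anc_c, n_div) if n_div else (anc_c.copy(), [])

    variants: dict[str, SequenceVariant] = {}
    truth: dict = {"edits": {}, "clade": {}, "dominants": []}
    lo, hi = config.variant_edit_range
    for clade, ancestor in (("C", anc_c), ("D", anc_d)):
        current = ancestor
        for d in range(config.n_clade_dominants):
            if d > 0:
                current, _ = _mutate(rng, current, config.dominant_spacing)
            dom_label = f"{clade}{d + 1}"
            variants[dom_label] = SequenceVariant(
                label=dom_label, clade=clade, sequence="".join(current), published=True
            )
            truth["clade"][dom_label] = clade
            truth["dominants"].append(dom_label)
            for s in range(config.n_satellites_per_dominant):
                n_edits = int(rng.integers(lo, hi + 1))
                sat_seq, positions = _mutate(rng, current, n_edits)
                sat_label = f"{dom_label}.{s + 1}"
                variants[sat_label] = SequenceVariant(
                    label=sat_label, clade=clade, sequence="".join(sat_seq)
                )
                truth["edits"][sat_label] = (dom_label, n_edits, positions)
                truth["clade"][sat_label] = clade
    for label in config.pseudogene_injection:
        if label not in variants:
            base = truth["dominants"][0]
            seq, positions = _mutate(
                rng, np.array(list(variants[base].sequence)), hi
            )
            variants[label] = SequenceVariant(
                label=label,
                clade=truth["clade"][base],
                sequence="".join(seq),
                pseudogene_flagged=True,
            )
            truth["edits"][label] = (base, hi, positions)
            truth["clade"][label] = variants[label].clade
        else:
            v = variants[label]
            variants[label] = SequenceVariant(
                label=v.label, clade=v.clade, sequence=v.sequence,
                published=v.published, pseudogene_flagged=True,
            )
    return variants, truth


def _base_weights(rng, labels, clades, d_rich: bool) -> np.ndarray:
    """Site-level community weights: one clade dominant, the other rare."""
    major, minor = ("D", "C") if d_rich else ("C", "D")
    w = np.empty(len(labels))
    for i, lab in enumerate(labels):
        w[i] = rng.gamma(3.0, 1.0) if clades[lab] == major else rng.gamma(0.3, 1.0)
    return w / w.sum()


def simulate_bundle(config: SimConfig, seed: int | None = None) -> tuple[DatasetBundle, dict]:
    """Simulate a full bundle (variants, adult+egg libraries, metadata, truth record)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    variants, truth = make_variants(config, seed=seed)
    labels = sorted(variants)
    clades = truth["clade"]
    alpha0 = config.dirichlet_concentration

    libraries: list[CloneLibrary] = []
    truth["weights"] = {}
    lo, hi = config.library_size_range
    for site in config.sites:
        d_rich = site in config.clade_d_sites
        site_w = _base_weights(rng, labels, clades, d_rich)
        for c in range(1, config.n_colonies + 1):
            colony = f"{site}-{c}"
            for year in config.years:
                colony_w = rng.dirichlet(alpha0 * site_w * len(labels) + 1e-6)
                egg_w = colony_w
                if config.egg_model == "shifted" and d_rich:
                    is_c = np.array([clades[l] == "C" for l in labels], dtype=float)
                    c_w = colony_w * is_c
                    if c_w.sum() > 0:
                        egg_w = (
                            config.shifted_c_weight * c_w / c_w.sum()
                            + (1 - config.shifted_c_weight) * colony_w
                        )
                for stage, w in (("adult", colony_w), ("egg", egg_w)):
                    size = int(rng.integers(lo, hi + 1))
                    draw = rng.multinomial(size, w)
                    counts = {
                        labels[i]: int(draw[i]) for i in np.flatnonzero(draw)
                    }
                    sample_id = f"{colony}-{year}-{stage}"
                    libraries.append(
                        CloneLibrary(
                            sample_id=sample_id,
                            colony_id=colony,
                            site=site,
                            year=year,
                            life_stage=stage,
                            morphology=config.site_morphology.get(site, "unknown"),
                            counts=counts,
                        )
                    )
                    truth["weights"][sample_id] = dict(zip(labels, map(float, w)))

    genotypes = None
    if config.with_genotypes:
        genotypes = _simulate_genotypes(rng, config)
    env: list[EnvSeries] = []
    if config.with_env:
        env = _simulate_env(rng, config)
    bundle = DatasetBundle(variants=variants, libraries=libraries, genotypes=genotypes, env=env)
    return bundle, truth


def _simulate_genotypes(rng: np.random.Generator, config: SimConfig) -> GenotypeTable:
    """Small synthetic diploid table: allele pool with Hamming-distance sequences."""
    n_alleles = 6
    length = 60
    base = rng.choice(_BASES, size=length)
    allele_seqs: dict[str, str] = {}
    for a in range(n_alleles):
        seq, _ = _mutate(rng, base, a) if a else (base.copy(), [])
        allele_seqs[f"a{a + 1}"] = "".join(seq)
    pool = list(allele_seqs)
    individuals = []
    groupings = {}
    for site in config.sites:
        for k in range(1, 7):
            ind = f"{site}-host{k}"
            a, b = rng.choice(len(pool), size=2)
            individuals.append((ind, pool[a], pool[b]))
            groupings[ind] = (
                config.site_morphology.get(site, "unknown"),
                site,
            )
    return GenotypeTable(
        individuals=individuals, groupings=groupings, allele_sequences=allele_seqs
    )


def _simulate_env(rng: np.random.Generator, config: SimConfig) -> list[EnvSeries]:
    """Site-shifted temperature and light series with diel structure."""
    out = []
    n = 144  # one day at 10-min intervals
    t = np.arange(n)
    for i, site in enumerate(config.sites):
        stamps = [f"t{k:03d}" for k in t]
        temp = 26.5 + 0.6 * i + 1.2 * np.sin(2 * np.pi * t / n) + rng.normal(0, 0.2, n)
        temp = np.round(temp / 0.2) * 0.2  # logger resolution -> heavy ties
        light = np.clip(
            (700 - 180 * i) * np.clip(np.sin(2 * np.pi * t / n), 0, None)
            + rng.normal(0, 30, n),
            0,
            None,
        )
        out.append(EnvSeries(site=site, variable="temperature", timestamps=stamps, values=temp))
        out.append(EnvSeries(site=site, variable="light", timestamps=stamps, values=light))
    return out


# ---------------------------------------------------------------------------
# the published-count fixture


def published_dataset(seed: int = 20120606) -> DatasetBundle:
    """The printed clone-count dataset with synthetic placeholder sequences.

    Counts and factor metadata exactly as printed (64 libraries: 32 adult +
    32 egg); sequences are synthetic stand-ins for the GenBank records, so
    count-only statistics (PSI, screening, clade tallies) are canonical while
    distance-dependent results from this fixture are not.
    """
    rng = np.random.default_rng(seed)
    labels = all_labels()
    length = 320
    anc_c = rng.choice(_BASES, size=length)
    anc_d, _ = _mutate(rng, anc_c, int(round(0.25 * length)))

    # dominants are the base types (no decimal); satellites hang off the
    # dominant their name points at; C32.x derive from C21.11 (closest
    # relative of the pseudogene pair)
    dominants = sorted({l.split(".")[0] for l in labels if "." not in l} | {"C32"})
    dom_seq: dict[str, np.ndarray] = {}
    for dom in sorted(dominants):
        if dom == "C32":
            continue
        ancestor = anc_d if dom.startswith("D") else anc_c
        seq, _ = _mutate(rng, ancestor, int(rng.integers(2, 5)))
        dom_seq[dom] = seq
    dom_seq["C32"] = _mutate(rng, dom_seq.get("C21", anc_c), 3)[0]

    variants: dict[str, SequenceVariant] = {}
    for label in labels:
        root = label.split(".")[0]
        if label in dom_seq or (label == root and root in dom_seq):
            seq = dom_seq[root]
        else:
            seq, _ = _mutate(rng, dom_seq[root], int(rng.integers(1, 4)))
        variants[label] = SequenceVariant(
            label=label,
            clade=label[0],
            sequence="".join(seq),
            published=label in PUBLISHED,
            pseudogene_flagged=label in PSEUDOGENES,
        )

    libraries: list[CloneLibrary] = []
    for site, year, colony, adult, egg, _ in PUBLISHED_ROWS:
        for stage, spec in (("adult", adult), ("egg", egg)):
            libraries.append(
                CloneLibrary(
                    sample_id=f"{site}-{colony}-{year}-{stage}",
                    colony_id=colony,
                    site=site,
                    year=year,
                    life_stage=stage,
                    morphology=morphology_for(site, colony),
                    counts=parse_counts(spec),
                )
            )
    return DatasetBundle(variants=variants, libraries=libraries)
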