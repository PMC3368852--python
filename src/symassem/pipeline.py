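"""End-to-end orchestration: screen -> distances -> networks -> per-colony stats
-> multifactor partitions -> host AMOVA -> environment summaries.

``run_all`` consumes a :class:`RunConfig` and emits a :class:`RunReport` whose
tables mirror the standard reporting surfaces: a per-colony table (variant
counts, clades per sample, PSI, Phi, p), partition tables for the built-in
designs, the host AMOVA table, and per-site environmental summaries. Analyses
whose inputs are absent are skipped with a logged notice; every random step is
seeded so report regeneration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .distance import clone_distance_matrix, sqrt_transform, variant_distance_matrix
from .envstats import kruskal_wallis, summarize
from .host import hier_amova
from .io import DatasetBundle, validate_bundle
from .network import build_network, parsimony_limit
from .pairwise import permutation_test, psi
from .partition import DesignSpec, builtin_designs, fit_partition
from .screening import ScreenReport, apply_screen, clade_count, screen_variants

log = logging.getLogger("symassem")

__all__ = ["RunConfig", "RunReport", "run_all"]


@dataclass
class RunConfig:
    """Knobs for a full pipeline run."""

    gap_mode: str = "fifth_state"
    confidence: float = 0.95
    n_permutations: int = 10000
    seed: int = 0
    screen: bool = True
    fit_designs: bool = True
    output_dir: str | None = None

    def provenance(self) -> dict:
        payload = {
            "version": __version__,
            "gap_mode": self.gap_mode,
            "confidence": self.confidence,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "screen": self.screen,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]
        return {**payload, "config_hash": digest}


@dataclass
class RunReport:
    """Every table the pipeline produces, plus provenance."""

    screen_report: ScreenReport
    colony_table: pd.DataFrame
    network_edges: dict[str, pd.DataFrame]
    partition_tables: dict[str, pd.DataFrame]
    host_table: pd.DataFrame | None
    env_summaries: pd.DataFrame | None
    env_tests: pd.DataFrame | None
    provenance: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.screen_report.write(outdir / "screen_report.tsv")
        self.colony_table.to_csv(outdir / "colony_table.tsv", sep="\t", index=False)
        for name, edges in self.network_edges.items():
            edges.to_csv(outdir / f"network_{name}.tsv", sep="\t", index=False)
        for name, tab in self.partition_tables.items():
            tab.to_csv(outdir / f"partition_{name}.tsv", sep="\t", index=False)
        if self.host_table is not None:
            self.host_table.to_csv(outdir / "host_amova.tsv", sep="\t", index=False)
        if self.env_summaries is not None:
            self.env_summaries.to_csv(outdir / "env_summaries.tsv", sep="\t", index=False)
        if self.env_tests is not None:
            self.env_tests.to_csv(outdir / "env_tests.tsv", sep="\t", index=False)
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))


def run_all(bundle: DatasetBundle, config: RunConfig | None = None) -> RunReport:
    """Execute the full analysis on a validated bundle."""
    config = config or RunConfig()
    findings = validate_bundle(bundle)
    errors = [f for f in findings if "unknown variant" in f or "unresolvable" in f]
    if errors:
        raise ValueError("bundle validation failed: " + "; ".join(errors))

    # 1. screening
    if config.screen:
        report = screen_variants(bundle.libraries, bundle.variants)
    else:
        observed = {l for lib in bundle.libraries for l in lib.counts}
        report = ScreenReport(retained=observed)
    screened = [apply_screen(lib, report) for lib in bundle.libraries]
    screened = [lib for lib in screened if not lib.is_empty()]

    # 2. distances
    retained_variants = [
        v for v in bundle.variants.values() if v.label in report.retained
    ]
    vmat = variant_distance_matrix(retained_variants, gap_mode=config.gap_mode)
    clone_mat, clone_meta = clone_distance_matrix(screened, vmat)

    # 3. parsimony networks, per clade
    aligned_length = len(retained_variants[0].sequence)
    limit = parsimony_limit(aligned_length, config.confidence)
    network_edges: dict[str, pd.DataFrame] = {}
    for clade in sorted({v.clade for v in retained_variants}):
        clade_variants = [v for v in retained_variants if v.clade == clade]
        if len(clade_variants) < 2:
            continue
        sub = variant_distance_matrix(clade_variants, gap_mode=config.gap_mode)
        counts: dict[str, dict[str, int]] = {}
        for lib in screened:
            for lab, c in lib.counts.items():
                if lab in {v.label for v in clade_variants}:
                    counts.setdefault(lab, {}).setdefault(lib.life_stage, 0)
                    counts[lab][lib.life_stage] += c
        net = build_network(sub, counts, limit)
        network_edges[f"clade_{clade}"] = pd.DataFrame(
            [{"from": u, "to": v, "steps": s} for u, v, s in net.edges()],
            columns=["from", "to", "steps"],
        )

    # 4. per-colony adult-vs-egg statistics
    rng = np.random.default_rng(config.seed)
    by_key: dict[tuple, dict[str, object]] = {}
    for lib in screened:
        by_key.setdefault((lib.site, lib.year, lib.colony_id), {})[lib.life_stage] = lib
    rows = []
    for (site, year, colony), pair in sorted(by_key.items(), key=lambda kv: str(kv[0])):
        if "adult" not in pair or "egg" not in pair:
            log.info("colony %s %s %s lacks a life stage after screening; skipped", site, year, colony)
            continue
        adult, egg = pair["adult"], pair["egg"]
        p = psi(adult, egg)
        res = permutation_test(
            adult, egg, clone_mat, clone_meta,
            n_perm=config.n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(
            {
                "site": site,
                "year": year,
                "colony_id": colony,
                "adult_total": adult.total,
                "egg_total": egg.total,
                "adult_clades": clade_count(adult, bundle.variants),
                "egg_clades": clade_count(egg, bundle.variants),
                "PSI": p.rounded,
                "phi": res.phi,
                "p": res.p_value,
            }
        )
    colony_table = pd.DataFrame(rows)

    # 5. multifactor partitions on sqrt-transformed distances
    partition_tables: dict[str, pd.DataFrame] = {}
    if config.fit_designs:
        sqrt_mat = sqrt_transform(clone_mat)
        four, three = builtin_designs()
        # four-factor design: single-morphology sites sampled across years;
        # three-factor design: sites where both morphologies co-occur
        morph_per_site = clone_meta.groupby("site")["morphology"].nunique()
        years_per_site = clone_meta.groupby("site")["year"].nunique()
        multimorph_sites = set(morph_per_site[morph_per_site > 1].index)
        four_sites = sorted(
            s for s in years_per_site.index
            if s not in multimorph_sites and years_per_site[s] > 1
        )
        four_mask = clone_meta["site"].isin(four_sites).to_numpy()
        if four_mask.sum() and clone_meta.loc[four_mask, "site"].nunique() > 1:
            partition_tables["four_factor"] = _fit_subset(
                sqrt_mat, clone_meta, four_mask, four, config
            )
        else:
            log.info("four-factor design skipped: fewer than 2 single-morphology sites")
        three_mask = clone_meta["site"].isin(sorted(multimorph_sites)).to_numpy()
        if three_mask.sum() and clone_meta.loc[three_mask, "morphology"].nunique() > 1:
            partition_tables["three_factor"] = _fit_subset(
                sqrt_mat, clone_meta, three_mask, three, config
            )
        else:
            log.info("three-factor design skipped: no site with both morphologies")

    # 6. host AMOVA
    host_table = None
    if bundle.genotypes is not None:
        host = hier_amova(
            bundle.genotypes,
            n_perm=min(config.n_permutations, 999),
            seed=config.seed,
        )
        host_table = host.summary()
    else:
        log.info("no genotypes supplied; host AMOVA skipped")

    # 7. environment
    env_summaries = env_tests = None
    if bundle.env:
        env_summaries = pd.DataFrame([vars(summarize(s)) for s in bundle.env])
        test_rows = []
        for variable in sorted({s.variable for s in bundle.env}):
            groups = [s.values for s in bundle.env if s.variable == variable]
            if len(groups) >= 2:
                h, df, pval = kruskal_wallis(groups)
                test_rows.append({"variable": variable, "H": h, "df": df, "p": pval})
        env_tests = pd.DataFrame(test_rows) if test_rows else None
    else:
        log.info("no environmental series supplied; env stats skipped")

    report = RunReport(
        screen_report=report,
        colony_table=colony_table,
        network_edges=network_edges,
        partition_tables=partition_tables,
        host_table=host_table,
        env_summaries=env_summaries,
        env_tests=env_tests,
        provenance=config.provenance(),
    )
    if config.output_dir:
        report.write(config.output_dir)
    return report


def _fit_subset(sqrt_mat, clone_meta, mask, design: DesignSpec, config: RunConfig) -> pd.DataFrame:
    from .distance import DistanceMatrix

    sub = DistanceMatrix(
        labels=[l for l, m in zip(sqrt_mat.labels, mask) if m],
        values=sqrt_mat.values[np.ix_(mask, mask)],
        metric=sqrt_mat.metric,
    )
    meta = clone_meta.loc[mask].reset_index(drop=True)
    table = fit_partition(
        sub, meta, design, n_perm=config.n_permutations, seed=config.seed
    )
    return table.summary()
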