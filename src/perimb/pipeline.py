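"""End-to-end workflow: simulate/load -> filter -> diversity -> statistics.

Every stage writes one artifact into the run directory and the manifest
records config, seeds and stage order, so re-running a manifest reproduces
all outputs bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .core import SampleMetadata
from .decontam import classify_contaminants, detect_batch_effects
from .diversity import alpha_diversity, pcoa, rarefy, weighted_unifrac
from .family import shared_asv_test, twin_bootstrap_test
from .stats import (DEFAULT_SCREEN_TARGETS, ancom, permanova, screen_targets,
                    summarize_clinical)
from .core import collapse_taxa
from .synth import Cohort, CohortConfig, generate_cohort, read_cohort, write_cohort

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report", "PipelineError"]

_CLINICAL_TERMS = [
    "Age", "PretermBirth37", "DeliveryMethod", "HasGDM", "IVFET", "Epidural",
    "InducedLabor", "Hypertension", "Weight", "HasTwins", "BabySex",
    "AntibioticsUse",
]

_ANCOM_VARIABLES = [
    "DeliveryMethod", "Epidural", "PretermBirth37", "HasGDM", "InducedLabor",
    "IVFET", "Hypertension", "AntibioticsUse", "BabySex",
]

_TWIN_SITES = ("AF", "CB", "GL", "M")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for one full run.

    Either ``cohort`` (simulate) or ``input_dir`` (load a written cohort)
    must be set.
    """

    cohort: CohortConfig | None = None
    input_dir: str | None = None
    rarefaction_depth: int = 5000
    decontam_threshold: float = 0.1
    decontam_method: str = "combined"
    permanova_terms: list = field(default_factory=lambda: ["site", "batch"]
                                  + _CLINICAL_TERMS)
    permanova_permutations: int = 199
    ancom_variables: list = field(default_factory=lambda: list(_ANCOM_VARIABLES))
    ancom_rank: int = 6               # genus
    twin_bootstrap: int = 1000
    twin_confidence: float = 0.95
    shared_random_pairs: int = 1000
    screen_targets: list = field(default_factory=lambda: list(DEFAULT_SCREEN_TARGETS))
    seed: int = 0

    def __post_init__(self):
        if self.cohort is None and self.input_dir is None:
            raise ValueError("config needs either 'cohort' or 'input_dir'")
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig.from_dict(self.cohort)

    def to_dict(self):
        d = {
            "cohort": self.cohort.to_dict() if self.cohort else None,
            "input_dir": self.input_dir,
            "rarefaction_depth": self.rarefaction_depth,
            "decontam_threshold": self.decontam_threshold,
            "decontam_method": self.decontam_method,
            "permanova_terms": list(self.permanova_terms),
            "permanova_permutations": self.permanova_permutations,
            "ancom_variables": list(self.ancom_variables),
            "ancom_rank": self.ancom_rank,
            "twin_bootstrap": self.twin_bootstrap,
            "twin_confidence": self.twin_confidence,
            "shared_random_pairs": self.shared_random_pairs,
            "screen_targets": list(self.screen_targets),
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d):
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage in order; returns the run directory.

    A stage failure aborts with :class:`PipelineError` naming the stage;
    artifacts already written are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done = []

    # -- acquire cohort ---------------------------------------------------
    @_stage("cohort")
    def _acquire() -> Cohort:
        if config.cohort is not None:
            cohort = generate_cohort(config.cohort)
            write_cohort(cohort, out / "cohort")
            return cohort
        return read_cohort(config.input_dir)

    cohort = _acquire()
    stages_done.append("cohort")
    table, metadata, tree, taxonomy = (cohort.table, cohort.metadata,
                                       cohort.tree, cohort.taxonomy)

    @_stage("batch_diagnostics")
    def _batch():
        diag = detect_batch_effects(table, metadata)
        pio.write_json({
            "ari_batch": diag.ari_batch, "ari_site": diag.ari_site,
            "excluded_samples": diag.excluded_samples,
            "cluster_labels": diag.cluster_labels.to_dict(),
        }, out / "batch_diagnostics.json")
        diag.correlation.to_csv(out / "sample_correlation.tsv", sep="\t")
        return diag

    _batch()
    stages_done.append("batch_diagnostics")

    @_stage("decontamination")
    def _decontam():
        rep = classify_contaminants(
            table, metadata, threshold=config.decontam_threshold,
            method=config.decontam_method)
        pio.write_json({
            "n_removed": rep.n_removed, "flagged": list(rep.flagged),
            "threshold": rep.threshold, "method": rep.method,
        }, out / "contaminants.json")
        rep.scores.to_csv(out / "contaminant_scores.tsv", sep="\t", index=False)
        pio.write_feature_table(rep.filtered_table, out / "filtered_table.tsv")
        return rep

    rep = _decontam()
    stages_done.append("decontamination")
    filtered = rep.filtered_table

    @_stage("rarefaction")
    def _rarefy():
        rt = rarefy(filtered, config.rarefaction_depth, seed=config.seed)
        if rt.n_samples == 0:
            raise ValueError(
                f"no sample reaches rarefaction depth {config.rarefaction_depth}")
        pio.write_feature_table(rt, out / "rarefied_table.tsv")
        return rt

    rarefied = _rarefy()
    stages_done.append("rarefaction")

    @_stage("alpha_diversity")
    def _alpha():
        alpha = alpha_diversity(rarefied)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        return alpha

    _alpha()
    stages_done.append("alpha_diversity")

    @_stage("beta_diversity")
    def _beta():
        dm = weighted_unifrac(rarefied.drop_empty_features(), tree)
        pio.write_distance_matrix(dm, out / "weighted_unifrac.tsv")
        return dm

    dm = _beta()
    stages_done.append("beta_diversity")

    @_stage("pcoa")
    def _pcoa():
        res = pcoa(dm)
        res.to_dataframe().to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        pio.write_json({
            "eigenvalues": res.eigenvalues,
            "proportion_explained": res.proportion_explained,
            "negative_eigenvalues": res.negative_eigenvalues,
        }, out / "pcoa.json")
        return res

    _pcoa()
    stages_done.append("pcoa")

    md = metadata.for_samples(dm.sample_ids)

    @_stage("permanova")
    def _permanova():
        results = {}
        terms_all = [t for t in config.permanova_terms if t in md.columns]
        results["all_sites"] = _try_permanova(dm, metadata, terms_all, config)
        for site in sorted(md["site"].unique()):
            ids = [s for s in dm.sample_ids if md.loc[s, "site"] == site]
            terms = [t for t in terms_all if t != "site"]
            if site == "AF":
                terms = [t for t in terms if t != "AntibioticsUse"]
            if len(ids) < 5:
                results[site] = {"error": "too few samples"}
                continue
            results[site] = _try_permanova(dm.submatrix(ids), metadata, terms,
                                           config)
        pio.write_json(results, out / "permanova.json")
        return results

    _permanova()
    stages_done.append("permanova")

    @_stage("ancom")
    def _ancom():
        genus_table = collapse_taxa(filtered, taxonomy, rank=config.ancom_rank)
        results = []
        for site in sorted(md["site"].unique()):
            site_ids = [s for s in genus_table.sample_ids
                        if s in md.index and md.loc[s, "site"] == site]
            sub = genus_table.select_samples(site_ids).drop_empty_features()
            for var in config.ancom_variables:
                if var not in md.columns:
                    continue
                cell = {"variable": var, "site": site}
                try:
                    res = ancom(sub, metadata.df.loc[site_ids], var)
                    hits = res.table[res.table["reject"]]
                    cell.update({
                        "status": "ok",
                        "low_w_artifact": res.low_w_artifact,
                        "hits": [
                            {"taxon": t, "W": int(r["W"]),
                             "direction": r["direction"]}
                            for t, r in hits.iterrows()
                        ],
                    })
                except (ValueError, KeyError) as exc:
                    cell.update({"status": "not_applicable", "reason": str(exc)})
                results.append(cell)
        pio.write_json(results, out / "ancom.json")
        return results

    _ancom()
    stages_done.append("ancom")

    @_stage("twin_tests")
    def _twins():
        results = {}
        for site in _TWIN_SITES:
            ids = [s for s in dm.sample_ids if md.loc[s, "site"] == site]
            if len(ids) < 3:
                results[site] = {"error": "too few samples"}
                continue
            site_dm = dm.submatrix(ids)
            per = {}
            import warnings as _w
            for stratum in ("all", "mono", "di"):
                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    res = twin_bootstrap_test(
                        site_dm, metadata, stratum=stratum,
                        n_bootstrap=config.twin_bootstrap,
                        confidence=config.twin_confidence, seed=config.seed)
                per[stratum] = res.to_dict()
            results[site] = per
        pio.write_json(results, out / "twin_tests.json")
        return results

    _twins()
    stages_done.append("twin_tests")

    @_stage("shared_asv")
    def _shared():
        res = shared_asv_test(filtered, metadata,
                              n_random_pairs=config.shared_random_pairs,
                              seed=config.seed)
        pio.write_json(res.to_dict(), out / "shared_asv.json")
        return res

    _shared()
    stages_done.append("shared_asv")

    @_stage("target_screen")
    def _screen():
        vd_ids = [s for s in filtered.sample_ids
                  if metadata.df.loc[s, "site"] == "VD"]
        if vd_ids:
            vd_table = filtered.select_samples(vd_ids)
            res = screen_targets(vd_table, taxonomy, config.screen_targets)
            res.abundances.to_csv(out / "screen_abundances.tsv", sep="\t")
            pio.write_json({"detected": res.detected,
                            "n_detected": res.n_detected},
                           out / "screen.json")
        else:
            pio.write_json({"detected": {}, "n_detected": 0,
                            "note": "no VD samples"}, out / "screen.json")

    _screen()
    stages_done.append("target_screen")

    @_stage("clinical_summary")
    def _clinical():
        mothers = metadata.df[metadata.df["role"] == "mother"]
        mothers = mothers.groupby("subject_id").head(1)
        spec = {}
        for var in ("Age", "Weight"):
            if var in mothers.columns:
                spec[var] = "continuous"
        for var in ("PretermBirth37", "HasGDM", "IVFET", "Epidural",
                    "InducedLabor", "Hypertension", "AntibioticsUse",
                    "HasTwins", "DeliveryMethod"):
            if var in mothers.columns:
                spec[var] = "categorical"
        rows = summarize_clinical(mothers, spec) if spec else []
        pio.write_json(rows, out / "clinical_summary.json")

    _clinical()
    stages_done.append("clinical_summary")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": stages_done,
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    pio.write_json(manifest, out / "manifest.json")
    return out


def _try_permanova(dm, metadata, terms, config):
    kept = list(terms)
    while kept:
        try:
            res = permanova(dm, metadata, kept,
                            n_permutations=config.permanova_permutations,
                            seed=config.seed)
            return {"terms": res.terms, "r2": res.r2, "p": res.p,
                    "df": res.df}
        except ValueError as exc:
            msg = str(exc)
            if "collinear" in msg:
                # drop the offending term and retry
                bad = msg.split("'")[1]
                kept = [t for t in kept if t != bad]
                continue
            return {"error": msg}
    return {"error": "no usable terms"}


def report(run_dir) -> str:
    """Human-readable summary of a completed run; returns the text."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = pio.read_json(manifest_path)
    lines = ["run summary", "===========", ""]
    lines.append(f"stages: {', '.join(manifest['stages'])}")

    def _load(name):
        p = run_dir / name
        if not p.exists():
            raise FileNotFoundError(f"missing stage output {name}")
        return pio.read_json(p)

    contaminants = _load("contaminants.json")
    lines.append(f"contaminant features removed: {contaminants['n_removed']}")
    batch = _load("batch_diagnostics.json")
    lines.append(f"cluster-batch ARI: {batch['ari_batch']:.3f}; "
                 f"cluster-site ARI: {batch['ari_site']:.3f}")
    perma = _load("permanova.json")
    allm = perma.get("all_sites", {})
    if "r2" in allm:
        site_r2 = allm["r2"].get("site")
        if site_r2 is not None:
            lines.append(f"PERMANOVA all-sites Site R2: {site_r2:.3f} "
                         f"(p={allm['p'].get('site'):.3g})")
    ancom_cells = _load("ancom.json")
    n_hits = sum(len(c.get("hits", [])) for c in ancom_cells)
    lines.append(f"ANCOM grid cells: {len(ancom_cells)}; rejected taxa: {n_hits}")
    twins = _load("twin_tests.json")
    for site, per in sorted(twins.items()):
        if "error" in per:
            continue
        r = per.get("all", {})
        lines.append(f"twin test {site} (all): reject={r.get('reject')} "
                     f"n_pairs={r.get('n_twin_pairs')}")
    shared = _load("shared_asv.json")
    lines.append(
        "shared ASVs: true pairs mean "
        f"{shared['mean_true_pairs']:.2f} vs random "
        f"{shared['mean_random_pairs']:.2f} (p={shared['p_value']:.3g})")
    screen = _load("screen.json")
    lines.append(f"screen targets detected: {screen['n_detected']}")
    clinical = _load("clinical_summary.json")
    lines.append(f"clinical summary rows: {len(clinical)}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
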