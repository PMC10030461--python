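"""Synthetic family-structured 16S cohort generator.

Emulates the design every downstream stage assumes: mothers (a fraction
carrying twins, monochorionic or dichorionic), maternal and neonatal body
sites, negative controls, batch-structured reagent contamination whose
per-sample load scales inversely with DNA concentration, and site-specific
community profiles with tunable family/twin similarity.

Generative model
----------------
* Per site, a base composition over the non-contaminant taxa is drawn from a
  symmetric Dirichlet with concentration ``site_effect`` (scalar, or a
  per-site mapping to tune site richness).
* Each subject perturbs the site base on the log scale.  The perturbation is
  a variance-one blend of an individual draw, a family-shared draw and (for
  twins) a twin-shared draw, with mixing weights ``1 : family_effect :
  twin_effect`` — so large effects shrink members toward the shared draw.
* Read counts are Multinomial(depth ~ Poisson(depth_mean), composition).
* ``n_contaminants`` dedicated taxa are mixed in per batch: a sample's total
  contaminant relative mass is ``contamination_strength / dna_concentration``
  (clipped), and contaminants dominate negative controls.  Concentrations are
  log-normal per site, lowest for AF/CB.
* ``batch_effect`` multiplies a batch-specific log-normal per-taxon factor
  into abundances before count drawing.
* A random coalescent-style tree with exponential branch lengths covers all
  taxa; lineage strings give every taxon a 7-rank taxonomy (two ASVs per
  genus so genus-level collapsing is non-trivial).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as pio
from .core import FeatureTable, RootedTree, SampleMetadata, Taxonomy
from .rng import substream

__all__ = ["CohortConfig", "Cohort", "CohortTruth", "generate_cohort",
           "write_cohort", "read_cohort"]

# genus pool; includes the vaginal-health screen defaults so the target screen
# finds hits on synthetic data
_GENUS_NAMES = [
    "Lactobacillus", "Gardnerella", "Prevotella", "Sneathia", "Aerococcus",
    "Fusobacterium", "Peptoniphilus", "Porphyromonas", "Streptococcus",
    "Staphylococcus", "Ureaplasma", "Bifidobacterium", "Finegoldia",
    "Bacteroides", "Corynebacterium", "Veillonella", "Enterococcus",
    "Escherichia", "Clostridium", "Actinomyces",
]

_CLINICAL_FLAGS = {
    # name -> prevalence among mothers
    "PretermBirth37": 0.26,
    "HasGDM": 0.14,
    "IVFET": 0.24,
    "Epidural": 0.48,
    "InducedLabor": 0.30,
    "Hypertension": 0.12,
    "AntibioticsUse": 0.20,
}

_CONC_LOGMEAN = {"VD": 3.5, "GL": 1.5, "M": 1.5, "AF": 0.3, "CB": 0.3}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort."""

    n_families: int = 30
    twin_fraction: float = 0.25
    mono_fraction_of_twins: float = 0.2
    sites_per_mother: tuple = ("VD", "AF")
    sites_per_neonate: tuple = ("CB", "GL", "M")
    n_negative_controls: int = 9
    n_batches: int = 3
    n_features: int = 80
    depth_mean: float = 2000.0
    site_effect: float | dict = 0.7
    family_effect: float = 0.0
    twin_effect: float = 0.0
    n_contaminants: int = 8
    contamination_strength: float = 2.0
    batch_effect: float = 0.4
    subject_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("twin_fraction", "mono_fraction_of_twins"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_families", "n_negative_controls", "n_batches",
                     "n_features", "n_contaminants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.n_contaminants > self.n_features:
            raise ValueError("n_contaminants cannot exceed n_features")
        for name in ("family_effect", "twin_effect", "contamination_strength",
                     "batch_effect", "subject_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        object.__setattr__(self, "sites_per_mother", tuple(self.sites_per_mother))
        object.__setattr__(self, "sites_per_neonate", tuple(self.sites_per_neonate))

    def site_concentration(self, site: str) -> float:
        if isinstance(self.site_effect, dict):
            return float(self.site_effect[site])
        return float(self.site_effect)

    def to_dict(self):
        d = asdict(self)
        d["sites_per_mother"] = list(self.sites_per_mother)
        d["sites_per_neonate"] = list(self.sites_per_neonate)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if isinstance(d.get("site_effect"), dict):
            d["site_effect"] = {k: float(v) for k, v in d["site_effect"].items()}
        return cls(**d)


@dataclass
class CohortTruth:
    """What was planted: contaminants, family structure, site profiles."""

    contaminant_ids: list
    families: list = field(default_factory=list)
    site_profiles: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "contaminant_ids": list(self.contaminant_ids),
            "families": self.families,
            "site_profiles": {k: list(map(float, v))
                              for k, v in self.site_profiles.items()},
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            contaminant_ids=list(d["contaminant_ids"]),
            families=list(d["families"]),
            site_profiles={k: np.asarray(v) for k, v in d["site_profiles"].items()},
        )


class Cohort(NamedTuple):
    table: FeatureTable
    metadata: SampleMetadata
    tree: RootedTree
    taxonomy: Taxonomy
    truth: CohortTruth


def _softmax(logp):
    z = logp - logp.max()
    e = np.exp(z)
    return e / e.sum()


def _subject_perturbation(cfg, family_draw, twin_draw, own_draw):
    fe, te = cfg.family_effect, cfg.twin_effect if twin_draw is not None else 0.0
    tot = 1.0 + fe + te
    delta = np.sqrt(1.0 / tot) * own_draw + np.sqrt(fe / tot) * family_draw
    if twin_draw is not None and te > 0:
        delta = delta + np.sqrt(te / tot) * twin_draw
    return delta


def _random_tree(feature_ids, rng) -> RootedTree:
    """Random binary topology via sequential pair-joining, Exp(1) lengths."""
    nodes = [TreeNode(name=fid, length=float(rng.exponential(1.0)))
             for fid in feature_ids]
    if len(nodes) == 1:
        root = TreeNode(children=nodes)
        return RootedTree(root)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(length=float(rng.exponential(1.0)),
                          children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=nodes)
    return RootedTree(root)


def _make_taxonomy(feature_ids, n_true) -> Taxonomy:
    lineages = {}
    for i, fid in enumerate(feature_ids):
        if i < n_true:
            g = i // 2  # two ASVs per genus
            name = _GENUS_NAMES[g % len(_GENUS_NAMES)]
            gid = f"{name}" if g < len(_GENUS_NAMES) else f"{name}_{g}"
            lineages[fid] = (
                f"d__Bacteria;p__Phylum{g % 5};c__Class{g % 5};"
                f"o__Order{g % 7};f__Family{g % 11};g__{gid};s__{name.lower()}_sp{i}"
            )
        else:
            k = i - n_true
            lineages[fid] = (
                f"d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;"
                f"o__Reagentales;f__Reagentaceae;g__Reagenticola{k};s__kitome{k}"
            )
    return Taxonomy(lineages, {fid: 0.99 for fid in feature_ids})


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cohort (table, metadata, tree, taxonomy, truth record)."""
    cfg = config
    seed = cfg.seed
    n_true = cfg.n_features - cfg.n_contaminants
    feature_ids = [f"ASV{i:04d}" for i in range(cfg.n_features)]
    true_ids = feature_ids[:n_true]
    contam_ids = feature_ids[n_true:]

    sites = sorted(set(cfg.sites_per_mother) | set(cfg.sites_per_neonate))
    base_profiles = {}
    for site in sites:
        rng = substream(seed, "site-profile", site)
        conc = cfg.site_concentration(site)
        base_profiles[site] = rng.dirichlet(np.full(n_true, conc))

    # batch-level nuisance: per-taxon log-normal factor + contaminant profile
    batch_names = [f"B{b + 1:02d}" for b in range(cfg.n_batches)]
    batch_logfactor = {}
    batch_contam_profile = {}
    for b, bname in enumerate(batch_names):
        rng = substream(seed, "batch", b)
        batch_logfactor[bname] = cfg.batch_effect * rng.standard_normal(n_true)
        if cfg.n_contaminants:
            batch_contam_profile[bname] = rng.dirichlet(
                np.full(cfg.n_contaminants, 2.0))

    # -- family / subject structure --------------------------------------
    families = []
    subjects = []  # (subject_id, family_id, role, twin_pair_id, chorionicity)
    rng_fam = substream(seed, "families")
    for f in range(cfg.n_families):
        fam_id = f"F{f:03d}"
        mother = f"{fam_id}-M"
        is_twin = rng_fam.random() < cfg.twin_fraction
        chor = "none"
        twin_pair = None
        neonates = []
        if is_twin:
            chor = ("mono" if rng_fam.random() < cfg.mono_fraction_of_twins
                    else "di")
            twin_pair = f"{fam_id}-T"
            neonates = [f"{fam_id}-N1", f"{fam_id}-N2"]
        else:
            rng_fam.random()  # keep stream aligned across configs
            neonates = [f"{fam_id}-N1"]
        families.append({
            "family_id": fam_id, "mother": mother, "neonates": neonates,
            "twin_pair_id": twin_pair, "chorionicity": chor,
        })
        subjects.append((mother, fam_id, "mother", None, "none"))
        for n in neonates:
            subjects.append((n, fam_id, "neonate", twin_pair,
                             chor if twin_pair else "none"))

    # clinical covariates, drawn per family (mother-level)
    clinical = {}
    for fam in families:
        rng = substream(seed, "clinical", fam["family_id"])
        row = {
            "Age": int(np.clip(np.round(rng.normal(34, 3.5)), 20, 45)),
            "Weight": float(np.round(rng.normal(70, 8), 1)),
            "DeliveryMethod": "cesarean" if rng.random() < 0.55 else "vaginal",
            "HasTwins": int(fam["twin_pair_id"] is not None),
        }
        for name, p in _CLINICAL_FLAGS.items():
            row[name] = int(rng.random() < p)
        clinical[fam["family_id"]] = row

    # subject-level perturbations
    fam_draw = {f["family_id"]: substream(seed, "family-draw", f["family_id"])
                .standard_normal(n_true) for f in families}
    twin_draw = {f["twin_pair_id"]: substream(seed, "twin-draw", f["twin_pair_id"])
                 .standard_normal(n_true)
                 for f in families if f["twin_pair_id"]}
    delta = {}
    for subj, fam_id, role, pair, _chor in subjects:
        own = substream(seed, "subject-draw", subj).standard_normal(n_true)
        tdraw = twin_draw.get(pair) if role == "neonate" else None
        delta[subj] = cfg.subject_sigma * _subject_perturbation(
            cfg, fam_draw[fam_id], tdraw, own)

    # -- samples ----------------------------------------------------------
    sample_rows = []  # metadata rows
    sample_ids = []
    compositions = []  # full-length composition per sample
    depths = []

    def _batch_of(index):
        return batch_names[index % cfg.n_batches]

    sample_index = 0
    for subj, fam_id, role, pair, chor in subjects:
        subj_sites = cfg.sites_per_mother if role == "mother" else cfg.sites_per_neonate
        clin = clinical[fam_id]
        rng_subj = substream(seed, "baby-sex", subj)
        baby_sex = "M" if rng_subj.random() < 0.5 else "F"
        for site in subj_sites:
            sid = f"{subj}-{site}"
            bname = _batch_of(sample_index)
            rng = substream(seed, "sample", sid)
            conc = float(np.exp(rng.normal(_CONC_LOGMEAN.get(site, 1.0), 0.5)))
            logp = np.log(base_profiles[site]) + delta[subj] + batch_logfactor[bname]
            true_comp = _softmax(logp)
            comp = np.zeros(cfg.n_features)
            if cfg.n_contaminants:
                w = float(np.clip(cfg.contamination_strength / conc, 0.0, 0.9))
                comp[:n_true] = (1.0 - w) * true_comp
                comp[n_true:] = w * batch_contam_profile[bname]
            else:
                comp[:n_true] = true_comp
            depth = int(rng.poisson(cfg.depth_mean))
            sample_ids.append(sid)
            compositions.append(comp)
            depths.append(depth)
            sample_rows.append({
                "sample_id": sid, "subject_id": subj, "family_id": fam_id,
                "role": role, "site": site, "batch": bname,
                "dna_concentration": conc, "is_negative_control": False,
                "twin_pair_id": pair, "chorionicity": chor,
                "BabySex": baby_sex, **clin,
            })
            sample_index += 1

    for k in range(cfg.n_negative_controls):
        sid = f"NC{k + 1:02d}"
        bname = batch_names[k % cfg.n_batches]
        rng = substream(seed, "sample", sid)
        comp = np.zeros(cfg.n_features)
        if cfg.n_contaminants:
            comp[n_true:] = 0.998 * batch_contam_profile[bname]
            comp[:n_true] = 0.002 / max(n_true, 1)
            depth = int(rng.poisson(0.5 * cfg.depth_mean))
        else:
            comp[:n_true] = 1.0 / max(n_true, 1)
            depth = int(rng.poisson(0.001 * cfg.depth_mean))
        sample_ids.append(sid)
        compositions.append(comp)
        depths.append(depth)
        sample_rows.append({
            "sample_id": sid, "subject_id": sid, "family_id": None,
            "role": "control", "site": "NC", "batch": bname,
            "dna_concentration": None, "is_negative_control": True,
            "twin_pair_id": None, "chorionicity": "none",
            "BabySex": None,
        })  # clinical covariates left missing for controls

    counts = np.zeros((len(sample_ids), cfg.n_features), dtype=np.int64)
    for i, sid in enumerate(sample_ids):
        rng = substream(seed, "counts", sid)
        comp = compositions[i]
        total = comp.sum()
        if depths[i] > 0 and total > 0:
            counts[i] = rng.multinomial(depths[i], comp / total)

    table = FeatureTable(tuple(sample_ids), tuple(feature_ids), counts)
    meta_df = pd.DataFrame(sample_rows).set_index("sample_id")
    metadata = SampleMetadata(meta_df)
    tree = _random_tree(feature_ids, substream(seed, "tree"))
    taxonomy = _make_taxonomy(feature_ids, n_true)
    truth = CohortTruth(
        contaminant_ids=contam_ids,
        families=families,
        site_profiles={s: p for s, p in base_profiles.items()},
    )
    return Cohort(table, metadata, tree, taxonomy, truth)


# -- on-disk layout: one file per format ---------------------------------

_FILES = {
    "table": "feature_table.tsv",
    "metadata": "metadata.tsv",
    "tree": "tree.nwk",
    "taxonomy": "taxonomy.tsv",
    "truth": "truth.json",
}


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write all cohort artifacts; returns the name->path mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    pio.write_feature_table(cohort.table, paths["table"])
    pio.write_metadata(cohort.metadata, paths["metadata"])
    pio.write_tree(cohort.tree, paths["tree"])
    pio.write_taxonomy(cohort.taxonomy, paths["taxonomy"])
    pio.write_json(cohort.truth.to_dict(), paths["truth"])
    return paths


def read_cohort(directory) -> Cohort:
    directory = Path(directory)
    paths = {k: directory / v for k, v in _FILES.items()}
    return Cohort(
        table=pio.read_feature_table(paths["table"]),
        metadata=pio.read_metadata(paths["metadata"]),
        tree=pio.read_tree(paths["tree"]),
        taxonomy=pio.read_taxonomy(paths["taxonomy"]),
        truth=CohortTruth.from_dict(pio.read_json(paths["truth"])),
    )
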