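"""Synthetic microbiome cohorts with planted, recoverable signal.

The generator emulates the statistical structure the knowledge-primed
architecture assumes: abundance signal is organised at the level of the
knowledge groups (genera, metabolite producer/consumer sets, communities)
rather than individual species.

Sampling scheme, per sample:

1. metadata categories are drawn from fixed categorical priors (uniform
   over age/BMI/body-site classes, balanced gender), and a project label;
2. the phenotype is drawn from a logit table conditioned on the sample's
   age and body site (so metadata genuinely carry phenotype information);
3. log relative abundances start from a Dirichlet baseline draw, receive
   additive log-fold shifts on the driver group of every class the sample
   belongs to (phenotype driver genera, age driver genera, body-site driver
   communities, BMI driver producer sets, gender driver consumer sets),
   plus i.i.d. log-normal noise and a per-project per-species offset, and
   are renormalised to percent (rows sum to 100 exactly);
4. metadata are masked missing-at-random at per-task rates.

Default rates mirror a large real corpus in which body site is always
recorded while age (~81%), gender (~30%) and BMI (~94%) are missing.
Regeneration with the same spec is bitwise identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from microkpnn_mt.dataio import AGE_CLASSES, BMI_CLASSES, GENDER_CLASSES, AbundanceTable, Dataset
from microkpnn_mt.knowledge import (
    HiddenSchema,
    MaskMatrix,
    MetabolicEdge,
    Role,
    build_hidden_schema,
    build_mask,
)

__all__ = ["SimSpec", "KnowledgeSet", "SimOutput", "ShiftScenario",
           "make_knowledge", "simulate_dataset", "make_shift_scenario"]


@dataclass(frozen=True)
class SimSpec:
    n_samples: int = 600
    n_species: int = 50
    n_metabolites: int = 10
    n_genera: int = 12
    n_communities: int = 5
    n_phenotypes: int = 4            # healthy + diseases
    n_body_sites: int = 3
    n_projects: int = 4
    # fraction of samples with the metadata value masked out
    missing_age: float = 0.81
    missing_gender: float = 0.30
    missing_bmi: float = 0.94
    missing_body_site: float = 0.0
    # log-fold shifts applied to the driver group of each class
    effect_disease: float = 2.5
    effect_age: float = 1.5
    effect_gender: float = 1.0
    effect_bmi: float = 1.0
    effect_body_site: float = 1.5
    noise_sigma: float = 0.3         # log-normal per-cell noise
    project_offset_sigma: float = 0.3  # per-project per-species log offsets
    metadata_phenotype_coupling: float = 1.0  # strength of the (age, site) -> phenotype logits
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_age", "missing_gender", "missing_bmi", "missing_body_site"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_samples", "n_species", "n_metabolites", "n_genera",
                     "n_communities", "n_phenotypes", "n_body_sites", "n_projects"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.n_genera < 6 + self.n_phenotypes:
            raise ValueError(
                "need n_genera >= 6 + n_phenotypes so age and phenotype classes "
                "get distinct driver genera"
            )
        if self.n_communities < self.n_body_sites:
            raise ValueError("need one driver community per body site")
        if self.n_metabolites < 6:
            raise ValueError(
                "need at least 6 metabolites (4 BMI driver producer sets + "
                "2 gender driver consumer sets)"
            )


@dataclass
class KnowledgeSet:
    """In-memory knowledge sources in the dialects the parsers consume."""

    species: list[str]
    edges: set[MetabolicEdge]
    taxmap: dict[str, str]
    commmap: dict[str, set[str]]

    def schema_and_mask(self) -> tuple[HiddenSchema, MaskMatrix]:
        schema = build_hidden_schema(self.species, self.edges, self.taxmap, self.commmap)
        return schema, build_mask(schema, self.species)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "metabolic_edges.tsv", "w") as fh:
            for e in sorted(self.edges, key=lambda e: (e.metabolite_id, e.role.value, e.species_id)):
                fh.write(f"{e.species_id}\t{e.metabolite_id}\t{e.role.value}\n")
        with open(out / "taxonomy.tsv", "w") as fh:
            for sp in self.species:
                if sp in self.taxmap:
                    fh.write(f"{sp}\t{self.taxmap[sp]}\n")
        with open(out / "communities.tsv", "w") as fh:
            for sp in self.species:
                for c in sorted(self.commmap.get(sp, ())):
                    fh.write(f"{sp}\t{c}\n")


def make_knowledge(spec: SimSpec, rng: np.random.Generator | None = None) -> KnowledgeSet:
    """Random knowledge sources: a balanced species -> genus partition,
    producer/consumer bipartite edges, and overlapping communities."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    species = [f"S{i:03d}" for i in range(spec.n_species)]

    # balanced genus partition via a shuffled round-robin
    order = rng.permutation(spec.n_species)
    taxmap = {species[i]: f"G{j % spec.n_genera:02d}" for j, i in enumerate(order)}

    edges: set[MetabolicEdge] = set()
    for m in range(spec.n_metabolites):
        met = f"M{m:02d}"
        size = int(rng.integers(2, max(3, spec.n_species // 8) + 1))
        chosen = rng.choice(spec.n_species, size=2 * size, replace=False)
        for i in chosen[:size]:
            edges.add(MetabolicEdge(species[i], met, Role.PRODUCER))
        for i in chosen[size:]:
            edges.add(MetabolicEdge(species[i], met, Role.CONSUMER))

    commmap: dict[str, set[str]] = {}
    for c in range(spec.n_communities):
        comm = f"C{c:02d}"
        size = int(rng.integers(max(2, spec.n_species // spec.n_communities // 2),
                                max(3, spec.n_species // 2)))
        for i in rng.choice(spec.n_species, size=size, replace=False):
            commmap.setdefault(species[i], set()).add(comm)
    return KnowledgeSet(species=species, edges=edges, taxmap=taxmap, commmap=commmap)


@dataclass
class SimOutput:
    dataset: Dataset
    knowledge: KnowledgeSet
    truth: dict
    spec: SimSpec

    def schema_and_mask(self) -> tuple[HiddenSchema, MaskMatrix]:
        return self.knowledge.schema_and_mask()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.abundance.to_frame().to_csv(out / "abundance.tsv", sep="\t")
        meta = self.dataset.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(out / "metadata.tsv", sep="\t", na_rep="NA")
        self.knowledge.write(out)
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "spec": asdict(self.spec),
                    "drivers": self.truth["drivers"],
                    "true_metadata": {
                        k: list(map(str, v)) for k, v in self.truth["true_metadata"].items()
                    },
                },
                fh,
                indent=1,
            )


def _group_indicator(members: list[list[int]], n_species: int) -> np.ndarray:
    out = np.zeros((len(members), n_species))
    for k, idx in enumerate(members):
        out[k, idx] = 1.0
    return out


def simulate_dataset(spec: SimSpec) -> SimOutput:
    """Generate one cohort (abundances + metadata + knowledge + ground truth)."""
    rng = np.random.default_rng(spec.seed)
    kn = make_knowledge(spec, rng)
    S = spec.n_species
    sp_index = {sp: i for i, sp in enumerate(kn.species)}

    # --- driver groups, aligned with the knowledge structure
    genus_members: dict[str, list[int]] = {}
    for sp, g in kn.taxmap.items():
        genus_members.setdefault(g, []).append(sp_index[sp])
    genera = sorted(genus_members)
    genus_pick = rng.permutation(len(genera))
    age_driver_genera = [genera[i] for i in genus_pick[:6]]
    dis_driver_genera = [genera[i] for i in genus_pick[6 : 6 + spec.n_phenotypes]]

    producers: dict[str, list[int]] = {}
    consumers: dict[str, list[int]] = {}
    for e in kn.edges:
        d = producers if e.role is Role.PRODUCER else consumers
        d.setdefault(e.metabolite_id, []).append(sp_index[e.species_id])
    mets = sorted(producers)
    met_pick = rng.permutation(len(mets))
    bmi_driver_mets = [mets[i] for i in met_pick[:4]]
    gender_driver_mets = [mets[i] for i in met_pick[4:6]]

    comm_members: dict[str, list[int]] = {}
    for sp, cs in kn.commmap.items():
        for c in cs:
            comm_members.setdefault(c, []).append(sp_index[sp])
    comms = sorted(comm_members)
    site_driver_comms = [comms[i] for i in rng.permutation(len(comms))[: spec.n_body_sites]]

    ind = {
        "age": _group_indicator([sorted(genus_members[g]) for g in age_driver_genera], S),
        "disease": _group_indicator([sorted(genus_members[g]) for g in dis_driver_genera], S),
        "bmi": _group_indicator([sorted(producers[m]) for m in bmi_driver_mets], S),
        "gender": _group_indicator([sorted(consumers[m]) for m in gender_driver_mets], S),
        "body_site": _group_indicator([sorted(comm_members[c]) for c in site_driver_comms], S),
    }
    effects = {
        "age": spec.effect_age,
        "disease": spec.effect_disease,
        "bmi": spec.effect_bmi,
        "gender": spec.effect_gender,
        "body_site": spec.effect_body_site,
    }

    n = spec.n_samples
    age = rng.integers(0, 6, size=n)
    gender = rng.integers(0, 2, size=n)
    bmi = rng.integers(0, 4, size=n)
    site = rng.integers(0, spec.n_body_sites, size=n)
    project = rng.integers(0, spec.n_projects, size=n)

    # phenotype ~ softmax(coupling * one-hot(preferred class of the sample's
    # (age, body site) cell)); the preference table tiles the classes evenly
    # over the 6 x n_body_sites cells so phenotype marginals stay balanced
    cells = 6 * spec.n_body_sites
    pref_flat = np.tile(np.arange(spec.n_phenotypes), cells // spec.n_phenotypes + 1)[:cells]
    rng.shuffle(pref_flat)
    pref_table = pref_flat.reshape(6, spec.n_body_sites)
    logits = np.zeros((n, spec.n_phenotypes))
    logits[np.arange(n), pref_table[age, site]] += spec.metadata_phenotype_coupling
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    phenotype = (rng.random(n)[:, None] > cum).sum(axis=1)

    proj_offsets = rng.normal(0.0, spec.project_offset_sigma, size=(spec.n_projects, S))

    base = rng.dirichlet(np.ones(S), size=n)
    log_ab = np.log(np.clip(base, 1e-12, None))
    log_ab += effects["age"] * ind["age"][age]
    log_ab += effects["gender"] * ind["gender"][gender]
    log_ab += effects["bmi"] * ind["bmi"][bmi]
    log_ab += effects["body_site"] * ind["body_site"][site]
    log_ab += effects["disease"] * ind["disease"][phenotype]
    log_ab += rng.normal(0.0, spec.noise_sigma, size=(n, S)) if spec.noise_sigma > 0 else 0.0
    log_ab += proj_offsets[project]
    w = np.exp(log_ab - log_ab.max(axis=1, keepdims=True))
    abundance = 100.0 * w / w.sum(axis=1, keepdims=True)

    sample_ids = [f"sample_{i:05d}" for i in range(n)]
    table = AbundanceTable(values=abundance, sample_ids=sample_ids, species_ids=list(kn.species))

    def mask_mar(values: list, rate: float) -> list:
        drop = rng.random(n) < rate
        return [None if d else v for v, d in zip(values, drop)]

    age_labels = [AGE_CLASSES[a] for a in age]
    gender_labels = [GENDER_CLASSES[g] for g in gender]
    bmi_labels = [BMI_CLASSES[b] for b in bmi]
    site_labels = [f"site_{s}" for s in site]
    pheno_labels = ["healthy" if p == 0 else f"disease_{p}" for p in phenotype]
    meta = pd.DataFrame(
        {
            "age": mask_mar(age_labels, spec.missing_age),
            "gender": mask_mar(gender_labels, spec.missing_gender),
            "bmi": mask_mar(bmi_labels, spec.missing_bmi),
            "body_site": mask_mar(site_labels, spec.missing_body_site),
            "phenotype": pheno_labels,
            "project_id": [f"P{p}" for p in project],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = {
        "drivers": {
            "age": {AGE_CLASSES[i]: f"genus_{g}" for i, g in enumerate(age_driver_genera)},
            "disease": {
                ("healthy" if i == 0 else f"disease_{i}"): f"genus_{g}"
                for i, g in enumerate(dis_driver_genera)
            },
            "bmi": {BMI_CLASSES[i]: f"{m}_production" for i, m in enumerate(bmi_driver_mets)},
            "gender": {GENDER_CLASSES[i]: f"{m}_consumption" for i, m in enumerate(gender_driver_mets)},
            "body_site": {f"site_{i}": f"community_{c}" for i, c in enumerate(site_driver_comms)},
        },
        "true_metadata": {
            "age": age_labels, "gender": gender_labels, "bmi": bmi_labels,
            "body_site": site_labels, "phenotype": pheno_labels,
        },
        "project_offsets": proj_offsets,
        "phenotype_preference_table": pref_table,
    }
    return SimOutput(dataset=Dataset(table, meta), knowledge=kn, truth=truth, spec=spec)


@dataclass
class ShiftScenario:
    train: Dataset
    test: Dataset
    sim: SimOutput
    train_projects: list[str]
    test_projects: list[str]


def make_shift_scenario(spec: SimSpec) -> ShiftScenario:
    """Project-held-out split: the metadata -> phenotype mechanism is shared,
    but per-project abundance offsets differ between the train and test
    project sets, emulating dataset shift across studies."""
    if spec.n_projects < 2:
        raise ValueError("need at least 2 projects to form a shift scenario")
    sim = simulate_dataset(spec)
    projects = [f"P{p}" for p in range(spec.n_projects)]
    n_train = (spec.n_projects + 1) // 2
    train_projects, test_projects = projects[:n_train], projects[n_train:]
    from microkpnn_mt.dataio import split_by_project

    train, test = split_by_project(sim.dataset, train_projects, test_projects)
    return ShiftScenario(train=train, test=test, sim=sim,
                         train_projects=train_projects, test_projects=test_projects)
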