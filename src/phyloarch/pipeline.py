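"""End-to-end analysis orchestration: indexes -> classes -> signal -> PGLS ->
ACE -> MuSSE family -> ordination, behind one declarative configuration.

Every stage is re-seeded deterministically from the master seed, all analytic
choices the method leaves open (class-test alpha, permutation counts, root
prior, root mode, survival conditioning) surface in the configuration with
their documented defaults, and a manifest (config hash, seeds, versions,
stage timings) accompanies every run so outputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import (CLASS_NAMES, Branch, IndividualArchitecture,
                           branching_index_table, integrative_index,
                           segregate_classes)
from .discrete import fit_mk_all, marginal_ace, select_model
from .modelsel import delta_table
from .ordination import pca_traits, permanova
from .pgls import correlation_table
from .signal import blomberg_k, pagel_lambda, signal_table
from .simulate import (SimulationConfig, generate_architecture_individuals,
                       simulate_bm_traits, simulate_correlated_trait,
                       simulate_musse)
from .sse import build_model_family, family_table, fit_family
from .traits import SpeciesTraitObservation, SpeciesTraitTable
from .tree import read_newick, write_newick

log = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "validate_inputs", "run_full_analysis",
           "make_synthetic_bundle", "read_individuals", "write_individuals",
           "index_observation"]


@dataclass
class AnalysisConfig:
    """Paths and analytic choices for one full run."""

    tree: str
    individuals: str
    traits: str
    states: str
    out_dir: str = "results"
    seed: int = 0
    alpha: float = 0.1               # class-segregation significance level
    k_classes: int = 3
    n_perm: int = 999
    root_prior: str = "uniform"      # ACE root prior
    sse_root_mode: str = "obs"       # FitzJohn weighting
    sse_condition_on_survival: bool = False
    musse_models: list = None        # None = full 15-model family
    musse_drop: list = field(default_factory=list)   # tips dropped before MuSSE
    unbounded_lambda: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------

def write_individuals(individuals, path):
    """Long CSV, one row per axis; leaf areas are a ';'-joined list (cm^2)."""
    rows = []
    counters: dict = {}
    for ind in individuals:
        counters[ind.species] = counters.get(ind.species, 0) + 1
        iid = counters[ind.species]
        rows.append({"species": ind.species, "individual": iid, "axis": "trunk",
                     "axis_id": 0, "length_cm": float(ind.trunk_length),
                     "leaf_areas_cm2": ";".join(repr(float(a)) for a in ind.trunk_leaf_areas),
                     "n_branches": ind.n_branches})
        for b_i, br in enumerate(ind.branches, start=1):
            rows.append({"species": ind.species, "individual": iid,
                         "axis": "branch", "axis_id": b_i,
                         "length_cm": float(br.cumulated_length),
                         "leaf_areas_cm2": ";".join(repr(float(a)) for a in br.leaf_areas),
                         "n_branches": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_individuals(path):
    df = pd.read_csv(path, dtype={"leaf_areas_cm2": str})
    out = []
    for (sp, iid), grp in df.groupby(["species", "individual"], sort=False):
        trunk = grp[grp.axis == "trunk"]
        if len(trunk) != 1:
            raise ValueError(f"{sp}/{iid}: expected exactly one trunk row")
        trow = trunk.iloc[0]
        branches = []
        for _, r in grp[grp.axis == "branch"].iterrows():
            las = tuple(float(x) for x in str(r.leaf_areas_cm2).split(";") if x)
            branches.append(Branch(float(r.length_cm), las))
        tlas = tuple(float(x) for x in str(trow.leaf_areas_cm2).split(";") if x)
        nb = int(trow.n_branches) if str(trow.n_branches) not in ("", "nan") \
            else len(branches)
        out.append(IndividualArchitecture(str(sp), float(trow.length_cm),
                                          tlas, tuple(branches), nb))
    return out


def read_states(path) -> dict:
    df = pd.read_csv(path)
    return {str(r.species): int(r.state) for r in df.itertuples()}


def index_observation(table: pd.DataFrame, scores: pd.Series):
    """Species-level observation of the integrative index from individual scores."""
    by_sp = {sp: scores[table.species == sp].to_numpy()
             for sp in table.species.unique()}
    return SpeciesTraitObservation.from_replicates(by_sp)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(config: AnalysisConfig):
    """Report-only checks: formats, species concordance, tree ultrametricity.

    Returns a list of (level, message); levels are "error" and "warning".
    The input files are never mutated.
    """
    issues = []
    paths = {"tree": config.tree, "individuals": config.individuals,
             "traits": config.traits, "states": config.states}
    for name, p in paths.items():
        if not Path(p).exists():
            issues.append(("error", f"{name} file missing: {p}"))
    if issues:
        return issues

    try:
        tree = read_newick(Path(config.tree).read_text())
        if not tree.is_ultrametric():
            issues.append(("warning", "tree is not ultrametric to 1e-6"))
        tips = set(tree.tip_labels)
    except Exception as exc:
        issues.append(("error", f"tree: {exc}"))
        tips = set()

    def species_of(reader, path, name):
        try:
            obj = reader(path)
            return obj
        except Exception as exc:
            issues.append(("error", f"{name}: {exc}"))
            return None

    inds = species_of(read_individuals, config.individuals, "individuals")
    traits = species_of(lambda p: SpeciesTraitTable.from_long(pd.read_csv(p)),
                        config.traits, "traits")
    states = species_of(read_states, config.states, "states")

    if tips:
        for name, sp in (("individuals",
                          {i.species for i in inds} if inds else set()),
                         ("traits", set(traits.species) if traits else set()),
                         ("states", set(states) if states else set())):
            extra = sorted(sp - tips)
            if extra:
                issues.append(("error",
                               f"{name}: species not on tree: {extra}"))
    return issues


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def _stage_seeds(master: int, names):
    ss = np.random.SeedSequence(master)
    kids = ss.spawn(len(names))
    return {n: int(k.generate_state(1)[0] % (2 ** 31)) for n, k in zip(names, kids)}


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage; write the report bundle; return the output paths.

    Any stage failure raises with the stage name; outputs of completed stages
    are preserved in ``out_dir``.
    """
    issues = validate_inputs(config)
    errors = [m for lv, m in issues if lv == "error"]
    if errors:
        raise ValueError("input validation failed:\n" + "\n".join(errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["signal", "pgls", "ordination", "musse"])
    manifest = {"version": __version__, "config_digest": config.digest(),
                "seed": config.seed, "stage_seeds": seeds, "stages": {}}
    outputs = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        tree = read_newick(Path(config.tree).read_text())
        individuals = read_individuals(config.individuals)
        traits = SpeciesTraitTable.from_long(pd.read_csv(config.traits))
        states = read_states(config.states)
        manifest["stages"][stage] = {"sec": time.perf_counter() - t0,
                                     "n_tips": tree.n_tips,
                                     "n_individuals": len(individuals),
                                     "n_traits": len(traits.traits)}

        # ---- indexes and classes -----------------------------------------
        stage = "index"
        t0 = time.perf_counter()
        table = branching_index_table(individuals)
        sp_means = table.groupby("species")[["photo", "explo"]].mean()
        ii = integrative_index(sp_means)
        ind_scores = ii.project(table)
        seg = segregate_classes(
            {sp: ind_scores[table.species == sp].to_numpy()
             for sp in sp_means.index},
            alpha=config.alpha, k=config.k_classes)
        idx_df = sp_means.copy()
        idx_df["integrative"] = ii.scores
        idx_df["arch_class"] = [seg.classes[s] for s in idx_df.index]
        idx_df["class_name"] = [CLASS_NAMES.get(seg.classes[s], str(seg.classes[s]))
                                for s in idx_df.index]
        idx_df["letters"] = [seg.letters[s] for s in idx_df.index]
        outputs["indexes"] = out / "indexes.csv"
        idx_df.sort_values("integrative").to_csv(outputs["indexes"])
        manifest["stages"][stage] = {"sec": time.perf_counter() - t0,
                                     "rho_spearman": ii.rho_spearman,
                                     "pc1_explained": ii.explained}

        # ---- phylogenetic signal -----------------------------------------
        stage = "signal"
        t0 = time.perf_counter()
        idx_obs = index_observation(table, ind_scores)
        sig = signal_table(tree, traits, n_perm=config.n_perm,
                           seed=seeds["signal"])
        lam = pagel_lambda(tree, idx_obs, unbounded=config.unbounded_lambda)
        kk = blomberg_k(tree, idx_obs, n_perm=config.n_perm,
                        seed=seeds["signal"])
        sig = pd.concat([pd.DataFrame([{
            "trait": "branching_index", "lambda": lam.estimate,
            "lambda_p": lam.p_value, "K": kk.estimate, "K_p": kk.p_value,
            "n": kk.n_species}]), sig], ignore_index=True)
        outputs["signal"] = out / "signal_table.csv"
        sig.to_csv(outputs["signal"], index=False)
        manifest["stages"][stage] = {"sec": time.perf_counter() - t0}

        # ---- PGLS ---------------------------------------------------------
        stage = "pgls"
        t0 = time.perf_counter()
        pg = correlation_table(tree, idx_obs, traits, seed=seeds["pgls"])
        outputs["pgls"] = out / "pgls_table.csv"
        pg.to_csv(outputs["pgls"], index=False)
        manifest["stages"][stage] = {"sec": time.perf_counter() - t0}

        # ---- ancestral states ----------------------------------------------
        stage = "ace"
        t0 = time.perf_counter()
        fits = fit_mk_all(tree, states, k=config.k_classes,
                          root_prior=config.root_prior)
        best = select_model(fits)
        outputs["mk_selection"] = out / "mk_model_selection.csv"
        delta_table(fits).to_csv(outputs["mk_selection"], index=False)
        from .discrete import MkModel
        probs, _ = marginal_ace(
            tree, states, MkModel(config.k_classes,
                                  best.params["constraint"],
                                  best.params["rates"]),
            root_prior=config.root_prior)
        ace_df = pd.DataFrame(
            [{"node": nid, **{f"P{state}": p[state - 1]
                              for state in range(1, config.k_classes + 1)}}
             for nid, p in sorted(probs.items())])
        outputs["ace"] = out / "ace_probabilities.csv"
        ace_df.to_csv(outputs["ace"], index=False)
        manifest["stages"][stage] = {"sec": time.perf_counter() - t0,
                                     "best_mk": best.model}

        # ---- MuSSE family ---------------------------------------------------
        stage = "musse"
        t0 = time.perf_counter()
        mtree = tree
        mstates = dict(states)
        if config.musse_drop:
            from .tree import prune_tips
            mtree = prune_tips(tree, config.musse_drop)
            mstates = {s: v for s, v in states.items()
                       if s not in set(config.musse_drop)}
        family = build_model_family()
        if config.musse_models:
            family = [p for p in family if p.name in set(config.musse_models)]
        fits = fit_family(mtree, mstates, family, seed=seeds["musse"],
                          root_mode=config.sse_root_mode,
                          condition_on_survival=config.sse_condition_on_survival)
        outputs["musse"] = out / "musse_family.csv"
        family_table(fits, family).to_csv(outputs["musse"], index=False)
        manifest["stages"][stage] = {"sec": time.perf_counter() - t0,
                                     "best_musse": select_model(fits).model}

        # ---- ordination -----------------------------------------------------
        stage = "ordination"
        t0 = time.perf_counter()
        ord_res = pca_traits(traits)
        outputs["ordination_scores"] = out / "ordination_scores.csv"
        outputs["ordination_loadings"] = out / "ordination_loadings.csv"
        ord_res.scores.to_csv(outputs["ordination_scores"])
        ord_res.loadings.to_csv(outputs["ordination_loadings"])
        groups = {s: seg.classes[s] for s in ord_res.scores.index
                  if s in seg.classes}
        perm = permanova(traits.means.loc[list(groups)], groups,
                         n_perm=config.n_perm, seed=seeds["ordination"])
        outputs["permanova"] = out / "permanova.json"
        with open(outputs["permanova"], "w") as fh:
            json.dump(dataclasses.asdict(perm), fh, indent=2)
        manifest["stages"][stage] = {"sec": time.perf_counter() - t0,
                                     "permanova_p": perm.p_value}
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    outputs["manifest"] = out / "manifest.json"
    with open(outputs["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    for name, p in outputs.items():
        log.info("wrote %s: %s", name, p)
    return {k: str(v) for k, v in outputs.items()}


# ---------------------------------------------------------------------------
# Synthetic bundle
# ---------------------------------------------------------------------------

def make_synthetic_bundle(out_dir, cfg: SimulationConfig = None,
                          n_null_traits: int = 2) -> AnalysisConfig:
    """Write a complete synthetic input bundle and its analysis config.

    The tree and architectural states come from a joint state-dependent
    birth-death simulation (resampled until every class has >= 2 species);
    individual measurements are calibrated to the class index means; the trait
    table holds one trait correlated with the integrative index (slope
    ``cfg.slope``) plus ``n_null_traits`` independent Brownian traits.
    """
    cfg = cfg or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = cfg.seed

    for attempt in range(cfg.max_retries):
        tree, states = simulate_musse(cfg.mussemodel(), cfg.n_species,
                                      root_state=cfg.root_state,
                                      seed=rng_seed + attempt,
                                      crown_age=cfg.crown_age)
        counts = np.bincount(list(states.values()), minlength=cfg.k_states + 1)[1:]
        if np.all(counts >= 2):
            break
    else:
        raise RuntimeError("could not simulate states with >= 2 species per class")

    (out / "tree.nwk").write_text(write_newick(tree) + "\n")
    pd.DataFrame({"species": list(states), "state": list(states.values())}) \
        .to_csv(out / "states.csv", index=False)

    individuals = generate_architecture_individuals(states, cfg,
                                                    seed=cfg.seed + 10_000)
    write_individuals(individuals, out / "individuals.csv")

    table = branching_index_table(individuals)
    sp_means = table.groupby("species")[["photo", "explo"]].mean()
    ii = integrative_index(sp_means)
    idx_obs = index_observation(table, ii.project(table))

    frames = []
    y, _, _ = simulate_correlated_trait(tree, idx_obs, cfg.slope, cfg.sigma2,
                                        cfg.within_sd, cfg.individuals,
                                        seed=cfg.seed + 20_000)
    frames.append(("corr_trait", y))
    for t in range(n_null_traits):
        obs, _, _ = simulate_bm_traits(tree, cfg.sigma2, cfg.lambda_signal,
                                       cfg.within_sd, cfg.individuals,
                                       seed=cfg.seed + 30_000 + t)
        frames.append((f"bm_trait_{t + 1}", obs))
    rows = []
    for name, obs in frames:
        for s, m, v, n in zip(obs.species, obs.mean, obs.variance, obs.n):
            rows.append({"species": s, "trait": name, "mean": m,
                         "variance": v, "n": n})
    pd.DataFrame(rows).to_csv(out / "traits.csv", index=False)

    config = AnalysisConfig(tree=str(out / "tree.nwk"),
                            individuals=str(out / "individuals.csv"),
                            traits=str(out / "traits.csv"),
                            states=str(out / "states.csv"),
                            out_dir=str(out / "results"), seed=cfg.seed)
    config.to_yaml(out / "config.yaml")
    return config
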