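"""End-to-end analysis pipeline: from tree + trait + predictor tables to the
full set of result tables.

Stages (each emits one CSV): Gaussian model selection per character,
phylogenetic signal, discrete-model tests (ER/ARD and the correlated-evolution
test), ancestral states per feather region, AICc-ranked PGLS model sets,
per-region phylogenetic ANOVA with Holm correction, and d-sep path-model
ranking.  A plain-text manifest records seeds, sample sizes, dropped taxa and
output hashes; re-running with identical inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evomodel_continuous as emc
from . import evomodel_discrete as emd
from . import path_analysis as pa
from . import phylo_anova as panova
from . import trait_scoring as ts
from .pgls_regression import rank_model_set
from .treekit import Phylogeny, is_ultrametric, read_newick

log = logging.getLogger("moltpath")

DEFAULT_MODEL_SETS = {
    "sd_extent": [
        ["pa_extent", "stratum_winter"],
        ["pa_extent", "stratum_breeding"],
        ["pa_extent", "stratum_winter", "day_length"],
        ["pa_extent"],
        ["migration_distance", "stratum_breeding"],
        ["migration_distance"],
        ["stratum_winter"],
        ["day_length"],
    ],
    "pa_extent": [
        ["migration_distance", "day_length"],
        ["migration_distance"],
        ["day_length"],
        ["stratum_breeding"],
        ["mass"],
    ],
}


@dataclass
class PipelineConfig:
    tree_path: str | None = None
    trait_path: str | None = None
    predictor_path: str | None = None
    dag_path: str | None = None
    out_dir: str = "moltpath_results"
    correlation: str = "BM"       # PGLS correlation structure
    n_sim: int = 1000             # phylogenetic-ANOVA null simulations
    seed: int = 1
    alpha: float = 0.05
    model_sets: dict = field(default_factory=lambda: {k: [list(m) for m in v]
                                                      for k, v in DEFAULT_MODEL_SETS.items()})
    regions: list = field(default_factory=lambda: list(ts.CANONICAL_REGIONS))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Input loading and reconciliation
# ---------------------------------------------------------------------------

def load_inputs(config: PipelineConfig):
    tree = read_newick(Path(config.tree_path).read_text())
    traits = pd.read_csv(config.trait_path, index_col=0)
    predictors = pd.read_csv(config.predictor_path, index_col=0)
    return reconcile(tree, traits, predictors, regions=config.regions)


def reconcile(tree: Phylogeny, traits: pd.DataFrame, predictors: pd.DataFrame,
              regions=None):
    """Prune tree and tables to their common species set; report both
    tree-only and table-only taxa."""
    tree_sp = set(tree.tip_labels)
    table_sp = set(traits.index) & set(predictors.index)
    common = sorted(tree_sp & table_sp)
    dropped = {"tree_only": sorted(tree_sp - table_sp),
               "table_only": sorted(table_sp - tree_sp)}
    if len(common) < 4:
        raise ValueError("fewer than 4 species shared between tree and tables")
    if len(common) < tree.n_tips:
        tree = tree.prune_to(common)
    order = list(tree.tip_labels)
    traits = traits.loc[order]
    predictors = predictors.loc[order]
    molt = ts.RegionScoreMatrix.from_frame(traits, "molt", regions)
    dich = ts.RegionScoreMatrix.from_frame(traits, "dichromatism", regions)
    return {"tree": tree, "molt": molt, "dichromatism": dich,
            "predictors": predictors, "dropped": dropped}


def analysis_frame(molt: ts.RegionScoreMatrix, dich: ts.RegionScoreMatrix,
                   predictors: pd.DataFrame) -> pd.DataFrame:
    """Combined per-species table used by PGLS, ANOVA and path stages."""
    df = predictors.copy()
    df["pa_extent"] = ts.extent(molt)
    df["pa_presence"] = ts.presence(molt)
    df["sd_extent"] = ts.extent(dich)
    df["sd_presence"] = ts.presence(dich)
    # short aliases for the path-analysis variable names
    df["migration"] = df["migration_distance"]
    df["daylength"] = df["day_length"]
    df["stratum"] = df.get("stratum_breeding", df.get("stratum"))
    df["molt"] = df["pa_extent"]
    df["dichromatism"] = df["sd_extent"]
    return df


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def model_selection_stage(tree, data: pd.DataFrame, characters: list) -> pd.DataFrame:
    """BM/OU/EB fits and AICc weights for each character (binary presence
    characters are fitted with the same Gaussian machinery and flagged)."""
    rows = []
    for char in characters:
        x = data[char].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            log.warning("skipping invariant character %s", char)
            continue
        fits = {m: emc.fit_model(tree, x, m) for m in ("BM", "OU", "EB")}
        w = emc.aicc_weights([fits[m].aicc for m in ("BM", "OU", "EB")])
        for (m, fit), wi in zip(fits.items(), w):
            rows.append({"character": char, "model": m, "sigma2": fit.sigma2,
                         "z0": fit.z0, "alpha": fit.alpha, "r": fit.r,
                         "lnL": fit.lnL, "k": fit.k, "aicc": fit.aicc,
                         "aicc_weight": wi,
                         "binary_trait": fit.meta.get("binary_trait", False)})
    return pd.DataFrame(rows)


def signal_stage(tree, data: pd.DataFrame, characters: list) -> pd.DataFrame:
    rows = []
    for char in characters:
        x = data[char].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        sig = emc.phylo_signal_lambda(tree, x)
        rows.append({"character": char, "lambda": sig["lambda"],
                     "lnL": sig["lnL"], "lnL_lambda0": sig["lnL_0"],
                     "lnL_lambda1": sig["lnL_1"]})
    return pd.DataFrame(rows)


def discrete_stage(tree, data: pd.DataFrame, pair: tuple = ("pa_presence",
                                                            "long_distance_migrant")):
    """ER vs ARD likelihood-ratio tests for presence characters plus the
    correlated-evolution (dependent vs independent) test for molt presence
    against long-distance migration."""
    rows = []
    for char in ("pa_presence", "sd_presence"):
        states = data[char].astype(int).tolist()
        if len(set(states)) < 2:
            continue
        er = emd.fit_mk(tree, states, "ER")
        ard = emd.fit_mk(tree, states, "ARD")
        test = emd.lrt(er.lnL, ard.lnL, df=ard.k - er.k)
        rows.append({"character": char, "test": "ER_vs_ARD",
                     "lnL_simple": er.lnL, "lnL_complex": ard.lnL,
                     "statistic": test["statistic"], "df": test["df"],
                     "p": test["p"], "rate_er": er.Q[0, 1],
                     "rate_01": ard.Q[0, 1], "rate_10": ard.Q[1, 0]})
    pagel = None
    x, y = (data[pair[0]].astype(int).tolist(), data[pair[1]].astype(int).tolist())
    if len(set(x)) == 2 and len(set(y)) == 2:
        pagel = emd.pagel_dependence_test(tree, y, x)  # first trait = migration
        rows.append({"character": f"{pair[0]}|{pair[1]}", "test": "pagel_dependence",
                     "lnL_simple": pagel["independent"].lnL,
                     "lnL_complex": pagel["dependent"].lnL,
                     "statistic": pagel["lrt"]["statistic"], "df": pagel["lrt"]["df"],
                     "p": pagel["lrt"]["p"],
                     "aic_independent": pagel["aic_independent"],
                     "aic_dependent": pagel["aic_dependent"]})
    return pd.DataFrame(rows), pagel


def asr_stage(tree, molt: ts.RegionScoreMatrix, dich: ts.RegionScoreMatrix):
    """Marginal ancestral presence probabilities per feather region (ER
    model), for each channel with enough variation."""
    frames = []
    for matrix in (molt, dich):
        pres = ts.presence_by_region(matrix)
        for region in matrix.regions:
            states = pres[region].astype(int).tolist()
            if len(set(states)) < 2:
                continue
            fit = emd.fit_mk(tree, states, "ER")
            asr = emd.marginal_asr(tree, states, fit.Q, fit.root_prior)
            trans = emd.count_transitions(asr, tree, states)
            df = pd.DataFrame({
                "channel": matrix.channel, "region": region,
                "node": asr.node_label,
                "p_absent": asr.probabilities[:, 0],
                "p_present": asr.probabilities[:, 1],
                "map_state": asr.map_states,
            })
            df["gains"] = trans["gains"]
            df["losses"] = trans["losses"]
            frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def pgls_stage(tree, data: pd.DataFrame, model_sets: dict,
               correlation: str = "BM") -> pd.DataFrame:
    tables = []
    for response, specs in model_sets.items():
        specs = [s for s in specs if all(c in data.columns for c in s)]
        if not specs:
            continue
        tables.append(rank_model_set(tree, data, response, specs, correlation))
    return pd.concat(tables, ignore_index=True)


def anova_stage(tree, molt: ts.RegionScoreMatrix, data: pd.DataFrame,
                response: str = "migration_distance", n_sim: int = 1000,
                seed: int = 1) -> pd.DataFrame:
    """Per-region phylogenetic ANOVA: the continuous response compared
    between species with and without molt in the region, Holm-corrected."""
    pres = ts.presence_by_region(molt)
    y = data[response].to_numpy(dtype=float)
    rows = []
    for i, region in enumerate(molt.regions):
        groups = pres[region].to_numpy()
        _, counts = np.unique(groups, return_counts=True)
        if len(counts) < 2 or counts.min() < 2:
            continue
        res = panova.phylo_anova(tree, y, groups, n_sim=n_sim, seed=seed + i,
                                 name=region)
        rows.append({"region": region, "F": res.F, "p": res.p,
                     "n_sim": res.n_sim, "seed": res.seed,
                     "degenerate": res.degenerate})
    table = pd.DataFrame(rows)
    if len(table):
        table["holm_p"] = panova.holm_adjust(table["p"].to_numpy())
    return table


def path_stage(tree, data: pd.DataFrame, dags=None, alpha: float = 0.05,
               correlation: str = "BM") -> pd.DataFrame:
    dags = dags if dags is not None else pa.default_dag_set()
    results = pa.evaluate_path_models(tree, data, dags, alpha=alpha,
                                      correlation=correlation)
    return pa.results_table(results)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_MAIN_CHARACTERS = ["pa_extent", "pa_presence", "sd_extent", "sd_presence"]


def run_pipeline(config: PipelineConfig, inputs: dict | None = None) -> dict:
    """Run every stage and write the seven result tables plus a manifest.

    ``inputs`` may carry pre-loaded objects (as produced by
    :func:`reconcile` or the synthetic generator) to bypass file loading.
    """
    if inputs is None:
        inputs = load_inputs(config)
    tree = inputs["tree"]
    molt, dich = inputs["molt"], inputs["dichromatism"]
    predictors = inputs["predictors"]
    dropped = inputs.get("dropped", {"tree_only": [], "table_only": []})
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = analysis_frame(molt, dich, predictors)
    if not is_ultrametric(tree):
        log.warning("input tree is not ultrametric; OU fits use the fixed-root form")

    characters = _MAIN_CHARACTERS + [c for c in data.columns
                                     if c.startswith(("pa_", "sd_"))
                                     and c not in _MAIN_CHARACTERS
                                     and not c.endswith(("extent", "presence"))]
    stages = {}
    stages["model_selection"] = model_selection_stage(tree, data, characters)
    stages["phylo_signal"] = signal_stage(tree, data, _MAIN_CHARACTERS)
    discrete_table, pagel = discrete_stage(tree, data)
    stages["discrete_tests"] = discrete_table
    stages["asr"] = asr_stage(tree, molt, dich)
    stages["pgls_ranking"] = pgls_stage(tree, data, config.model_sets,
                                        config.correlation)
    stages["phylo_anova"] = anova_stage(tree, molt, data, n_sim=config.n_sim,
                                        seed=config.seed)
    dags = pa.read_dag_set(config.dag_path) if config.dag_path else None
    stages["path_models"] = path_stage(tree, data, dags, alpha=config.alpha,
                                       correlation=config.correlation)

    hashes = {}
    for name, table in stages.items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.10g")
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    manifest = {
        "n_species": tree.n_tips,
        "seed": config.seed,
        "n_sim": config.n_sim,
        "correlation": config.correlation,
        "ultrametric": bool(is_ultrametric(tree)),
        "dropped_tree_only": dropped["tree_only"],
        "dropped_table_only": dropped["table_only"],
        "output_sha256": hashes,
    }
    with open(out / "manifest.txt", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    stages["manifest"] = manifest
    if pagel is not None:
        stages["pagel"] = pagel
    return stages
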