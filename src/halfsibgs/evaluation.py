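"""Replicated k-fold cross-validation and the model comparison runner.

Predictive ability is the Pearson correlation between predicted breeding
values and the block-adjusted phenotype of the validation individuals,
r(GEBV, y_adj).  A run's headline number is two-level: the mean over folds
within a replicate, then the mean of the replicate means — never a pooled
correlation.  Fold assignments are shared across models within a replicate
so model contrasts are paired.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, RelationshipMatrix, SnpPanel, TraitData
from .mixed_model import ablup, gblup, predict_gebv

logger = logging.getLogger(__name__)

__all__ = [
    "CvPlan",
    "CvResult",
    "make_cv_plan",
    "predictive_ability",
    "run_comparison",
]

MODELS = ("ABLUP", "GBLUP", "BayesB", "BLUPGA")


@dataclass
class CvPlan:
    """Replicate × individual fold assignments for k-fold CV."""

    n: int
    k: int
    reps: int
    assignments: np.ndarray  # (reps, n) fold index per individual
    seed: int

    def validation_indices(self, rep: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments[rep] == fold)


@dataclass
class CvResult:
    """Per-fold abilities for one model × trait × panel cell."""

    model: str
    trait: str
    panel: str
    fold_abilities: pd.DataFrame  # columns rep, fold, ability, omega_argmax

    @property
    def rep_means(self) -> pd.Series:
        return self.fold_abilities.groupby("rep")["ability"].mean()

    @property
    def overall_ability(self) -> float:
        """Mean of replicate means (the two-level average)."""
        return float(self.rep_means.mean())


def make_cv_plan(n: int, k: int = 6, reps: int = 10, seed: int = 0) -> CvPlan:
    """Random k-fold partitions, one per replicate, deterministic in seed.

    Every individual lands in exactly one validation fold per replicate and
    fold sizes differ by at most one (n = 468, k = 6 gives six folds of 78).
    """
    if n < k:
        raise ValueError("need at least k individuals")
    rng = np.random.default_rng(seed)
    base, rem = divmod(n, k)
    sizes = [base + 1 if f < rem else base for f in range(k)]
    labels = np.concatenate([np.full(sz, f, dtype=int) for f, sz in enumerate(sizes)])
    assignments = np.stack([rng.permutation(labels) for _ in range(reps)])
    return CvPlan(n=n, k=k, reps=reps, assignments=assignments, seed=seed)


def predictive_ability(gebv, y_adj) -> float:
    """Sample Pearson correlation r(GEBV, y_adj) on a validation set.

    A constant input vector leaves the correlation undefined; that case is
    reported as NaN with a warning, never silently coerced to zero.
    """
    gebv = np.asarray(gebv, dtype=float)
    y_adj = np.asarray(y_adj, dtype=float)
    if gebv.shape != y_adj.shape or gebv.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(gebv) == 0 or np.std(y_adj) == 0:
        warnings.warn("constant vector: predictive ability undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(gebv, y_adj)[0, 1])


def _bayesb_fold(g, trait, val_idx, priors, seed):
    from .bayesb import fit_bayesb, gebv_from_effects

    train_mask = np.ones(g.n_individuals, dtype=bool)
    train_mask[val_idx] = False
    g_train = GenotypeMatrix(
        g.dosage[train_mask], g.snp_meta,
        [s for s, t in zip(g.sample_ids, train_mask) if t],
    )
    eff = fit_bayesb(g_train, trait.y_adj[train_mask], priors, seed=seed)
    g_val = GenotypeMatrix(
        g.dosage[val_idx], g.snp_meta, [g.sample_ids[i] for i in val_idx]
    )
    return gebv_from_effects(g_val, eff)


def run_comparison(genotypes: GenotypeMatrix, pedigree: pd.DataFrame,
                   traits: dict, panels: list[SnpPanel],
                   plan: CvPlan, models=MODELS,
                   blupga_config=None, tune_bayesb: bool = True,
                   seed: int = 0):
    """Full model × trait × panel comparison under a shared CV plan.

    ``traits`` maps name -> TraitData (``y_adj`` filled by
    :func:`halfsibgs.synthetic_data.adjust_phenotypes`).  BayesB
    hyperparameters are tuned once per trait × panel on the folds of the
    first replicate and then held fixed for all replicates.  ABLUP does not
    depend on the SNP panel, so its fit is computed once per trait and its
    row repeated per panel.  Any model failure is recorded for that cell
    and the run continues.

    Returns
    -------
    (list[CvResult], DataFrame, list[(trait, panel, OmegaProfile)])
        Results, the long-format table (trait, panel, model, rep, fold,
        ability, omega_argmax), and all BLUP|GA ω profiles.
    """
    from .bayesb import BayesBPriors, tune_hyperparameters
    from .blupga import BlupGaConfig, blupga_predict
    from .kinship import build_G, build_pedigree_A

    blupga_config = blupga_config or BlupGaConfig()
    A = build_pedigree_A(pedigree) if "ABLUP" in models else None
    ids = list(genotypes.sample_ids)

    results: list[CvResult] = []
    profiles_log = []
    rows = []
    ablup_cache: dict[str, list[dict]] = {}

    for trait_name, trait in traits.items():
        if trait.y_adj is None:
            raise ValueError(f"trait {trait_name!r} lacks y_adj")
        for panel in panels:
            gp = genotypes.subset_snps(panel.snp_indices).recompute_freq()
            G = build_G(gp) if set(models) & {"GBLUP", "BLUPGA"} else None
            tuned = BayesBPriors()
            if "BayesB" in models and tune_bayesb:
                tuned, _ = tune_hyperparameters(
                    gp, trait.y_adj, plan.assignments[0], seed=seed
                )
                logger.info(
                    "tuned BayesB for %s/%s: nu=%g kappa=%g",
                    trait_name, panel.name, tuned.nu, tuned.kappa,
                )
            cell_rows: dict[str, list[dict]] = {m: [] for m in models}
            for rep in range(plan.reps):
                for fold in range(plan.k):
                    val_idx = plan.validation_indices(rep, fold)
                    val_ids = [ids[i] for i in val_idx]
                    y_val = trait.y_adj[val_idx]
                    for model in models:
                        if model == "ABLUP" and trait_name in ablup_cache:
                            continue
                        try:
                            omega_argmax = np.nan
                            if model == "ABLUP":
                                fit = ablup(trait, A, validation_ids=val_ids)
                                gebv = predict_gebv(fit, val_ids)
                                ability = predictive_ability(gebv, y_val)
                            elif model == "GBLUP":
                                fit = gblup(trait, G, validation_ids=val_ids)
                                gebv = predict_gebv(fit, val_ids)
                                ability = predictive_ability(gebv, y_val)
                            elif model == "BayesB":
                                gebv = _bayesb_fold(gp, trait, val_idx, tuned, seed)
                                ability = predictive_ability(gebv, y_val)
                            elif model == "BLUPGA":
                                profile, _ = blupga_predict(
                                    gp, trait, val_ids, G, blupga_config, seed=seed
                                )
                                ability = profile.max_ability
                                omega_argmax = profile.argmax_omega
                                profiles_log.append((trait_name, panel.name, profile))
                            else:
                                raise ValueError(f"unknown model {model!r}")
                            cell_rows[model].append(
                                {"rep": rep, "fold": fold, "ability": ability,
                                 "omega_argmax": omega_argmax}
                            )
                        except Exception as exc:
                            logger.warning(
                                "%s failed for %s/%s rep %d fold %d: %s",
                                model, trait_name, panel.name, rep, fold, exc,
                            )
            if "ABLUP" in models:
                if trait_name not in ablup_cache:
                    ablup_cache[trait_name] = cell_rows["ABLUP"]
                cell_rows["ABLUP"] = ablup_cache[trait_name]
            for model in models:
                df = pd.DataFrame(cell_rows[model])
                results.append(
                    CvResult(model=model, trait=trait_name, panel=panel.name,
                             fold_abilities=df)
                )
                for _, r in df.iterrows():
                    rows.append(
                        {"trait": trait_name, "panel": panel.name, "model": model,
                         "rep": int(r["rep"]), "fold": int(r["fold"]),
                         "ability": r["ability"],
                         "omega_argmax": r["omega_argmax"]}
                    )

    long_table = pd.DataFrame(rows)
    return results, long_table, profiles_log


def summarize(results: list[CvResult]) -> pd.DataFrame:
    """Trait × panel × model table of overall (rep-mean-of-fold-mean) ability."""
    return pd.DataFrame(
        [
            {"trait": r.trait, "panel": r.panel, "model": r.model,
             "ability": r.overall_ability}
            for r in results
        ]
    )
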