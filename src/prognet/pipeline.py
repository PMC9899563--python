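"""End-to-end orchestration: data -> imputation -> weights -> 18 models -> report.

Drives the full comparison of the nine modelling approaches for both
outcomes from a single configuration with a master seed. Test studies
never participate in imputation-model fitting, network estimation, factor
analysis, elastic-net tuning or regression fitting; the pipeline verifies
this with a before/after hash of the test tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cfa as cfa_mod
from .centrality import WeightVector, centrality_weight_vector
from .evaluate import (
    CalibrationBins,
    MetricSet,
    SeverityTable,
    binary_metrics,
    calibration_bins,
    continuous_metrics,
    prediction_correlations,
    severity_category_remission,
)
from .fgl import AdmmOptions, NetworkModel, fit_fgl, select_penalties, standardized_covariances
from .impute import ImputePolicy, filter_test_outcomes, impute_tables
from .models import (
    MODEL_IDS,
    EnrOptions,
    FittedModel,
    ModelSpec,
    fit_enr,
    fit_null,
    fit_regression,
    model_spec,
    predict,
    stratified_fold_labels,
)
from .scores import ScoreSet, item_level_predictors, unweighted_scores, weighted_scores
from .synthetic import (
    GeneratorConfig,
    StudyTable,
    generate_multi_study,
    inject_missingness,
    read_cohort,
)
from .variables import OUTCOME, REMISSION

logger = logging.getLogger("prognet")


@dataclass
class FglOptions:
    lambda1_grid: list[float] = field(
        default_factory=lambda: list(np.round(np.logspace(np.log10(0.01), 0.0, 10), 4))
    )
    lambda2_grid: list[float] = field(default_factory=lambda: [0.0, 0.01, 0.05, 0.1, 0.5])
    cv_folds: int = 10
    admm: AdmmOptions = field(default_factory=AdmmOptions)


@dataclass
class PipelineOptions:
    fgl: FglOptions = field(default_factory=FglOptions)
    enr: EnrOptions = field(default_factory=EnrOptions)
    walktrap_steps: int = 4


@dataclass
class RunConfig:
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    data_dir: str | None = None  # CSV cohort directory, alternative to generator
    missingness_scope: str = "baseline_only"
    impute: ImputePolicy = field(default_factory=ImputePolicy)
    options: PipelineOptions = field(default_factory=PipelineOptions)
    outcomes: tuple[str, ...] = ("continuous", "remission")
    bin_size: int = 50
    internal_cv_folds: int = 10
    run_internal_cv: bool = True
    internal_cv_models: tuple[int, ...] = MODEL_IDS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "generator" in raw:
            cfg.generator = GeneratorConfig(**raw["generator"]) if raw["generator"] else None
        if "data_dir" in raw:
            cfg.data_dir = raw["data_dir"]
        if "impute" in raw:
            cfg.impute = ImputePolicy(**raw["impute"])
        opts = raw.get("options", {})
        if "fgl" in opts:
            fgl_raw = dict(opts["fgl"])
            admm = AdmmOptions(**fgl_raw.pop("admm", {}))
            cfg.options.fgl = FglOptions(**fgl_raw, admm=admm)
        if "enr" in opts:
            cfg.options.enr = EnrOptions(**opts["enr"])
        if "walktrap_steps" in opts:
            cfg.options.walktrap_steps = opts["walktrap_steps"]
        for key in ("missingness_scope", "bin_size", "internal_cv_folds",
                    "run_internal_cv", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "outcomes" in raw:
            cfg.outcomes = tuple(raw["outcomes"])
        if "internal_cv_models" in raw:
            cfg.internal_cv_models = tuple(raw["internal_cv_models"])
        return cfg


def _child_seeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _hash_tables(tables: list[StudyTable]) -> str:
    h = hashlib.sha256()
    for t in tables:
        h.update(t.study_id.encode())
        h.update(pd.util.hash_pandas_object(t.data, index=True).to_numpy().tobytes())
    return h.hexdigest()


def estimate_weights(
    train_tables: list[StudyTable], options: PipelineOptions, seed: int
) -> tuple[dict[str, WeightVector], NetworkModel]:
    """Training-only weight estimation: FGL network with CV-selected
    penalties -> three centrality weight vectors, plus CFA loadings."""
    l1, l2 = select_penalties(
        train_tables,
        options.fgl.lambda1_grid,
        options.fgl.lambda2_grid,
        folds=options.fgl.cv_folds,
        seed=seed,
        options=options.fgl.admm,
    )
    logger.info("FGL penalties selected: lambda1=%g lambda2=%g", l1, l2)
    S_list, n_list = standardized_covariances(train_tables)
    network = fit_fgl(S_list, n_list, l1, l2, options.fgl.admm)
    weights = {
        m: centrality_weight_vector(network, m, options.walktrap_steps)
        for m in ("EI1", "EI2", "PCPR")
    }
    loadings = cfa_mod.fit_one_factor(train_tables)
    weights["CFA"] = cfa_mod.loadings_to_weights(loadings)
    return weights, network


def _score_set_for(
    spec: ModelSpec, tables: list[StudyTable], weights: dict[str, WeightVector]
) -> ScoreSet | None:
    if spec.form == "weighted_sums":
        return weighted_scores(tables, weights[spec.weighting])
    if spec.form == "unweighted_sums":
        return unweighted_scores(tables)
    if spec.form == "item_level":
        return item_level_predictors(tables)
    return None  # null model


def _outcome_vector(tables: list[StudyTable], outcome: str) -> np.ndarray:
    pooled = pd.concat([t.data for t in tables], ignore_index=True)
    col = OUTCOME if outcome == "continuous" else REMISSION
    return pooled[col].to_numpy(dtype=float)


def fit_all_models(
    train_tables: list[StudyTable],
    weights: dict[str, WeightVector],
    options: PipelineOptions,
    seed: int,
    outcomes: tuple[str, ...] = ("continuous", "remission"),
) -> dict[tuple[int, str], FittedModel]:
    """Fit the nine approaches for each requested outcome on training data."""
    fitted: dict[tuple[int, str], FittedModel] = {}
    for outcome in outcomes:
        family = "gaussian" if outcome == "continuous" else "binomial"
        y = _outcome_vector(train_tables, outcome)
        for mid in MODEL_IDS:
            spec = model_spec(mid, outcome)
            scores = _score_set_for(spec, train_tables, weights)
            if spec.estimator == "null":
                fm = fit_null(y, family)
            elif spec.estimator == "ENR":
                fm = fit_enr(scores, y, family, options.enr, seed=seed)
            else:
                fm = fit_regression(scores, y, family)
            fm.spec = spec
            fitted[(mid, outcome)] = fm
            logger.info("fitted model %d (%s)", mid, outcome)
    return fitted


def predict_models(
    fitted: dict[tuple[int, str], FittedModel],
    tables: list[StudyTable],
    weights: dict[str, WeightVector],
) -> dict[tuple[int, str], np.ndarray]:
    preds = {}
    for (mid, outcome), fm in fitted.items():
        scores = _score_set_for(fm.spec, tables, weights)
        if scores is None:
            n = sum(t.n for t in tables)
            preds[(mid, outcome)] = np.full(n, fm.null_value)
        else:
            preds[(mid, outcome)] = predict(fm, scores)
    return preds


def cross_validated_predictions(
    train_tables: list[StudyTable],
    specs: list[ModelSpec],
    folds: int = 10,
    seed: int = 0,
    options: PipelineOptions | None = None,
) -> dict[tuple[int, str], tuple[np.ndarray, np.ndarray]]:
    """Pooled held-out predictions from k-fold CV of the full pipeline.

    Weight estimation (network + CFA) and elastic-net tuning are re-run on
    each fold's training portion; per-fold weight estimation is shared
    across the requested specs. Returns (observed, predicted) pairs pooled
    over folds, keyed by (model_id, outcome).
    """
    options = options or PipelineOptions()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    pooled = pd.concat([t.data for t in train_tables], ignore_index=True)
    seeds = _child_seeds(seed, folds + 1)
    rng = np.random.default_rng(seeds[0])
    fold = stratified_fold_labels(pooled["study_id"], folds, rng)

    n = len(pooled)
    out: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
    store = {
        (s.model_id, s.outcome): np.full(n, np.nan) for s in specs
    }
    needs_weights = any(s.form == "weighted_sums" for s in specs)

    offsets = np.cumsum([0] + [t.n for t in train_tables])
    for f in range(folds):
        tr_tables, ho_tables = [], []
        ho_rows = np.flatnonzero(fold == f)
        for t, a, b in zip(train_tables, offsets[:-1], offsets[1:]):
            local = fold[a:b]
            tr_tables.append(
                StudyTable(t.study_id, t.role, t.data[local != f].reset_index(drop=True))
            )
            ho_tables.append(
                StudyTable(t.study_id, t.role, t.data[local == f].reset_index(drop=True))
            )
        try:
            weights, _ = (
                estimate_weights(tr_tables, options, seeds[f + 1])
                if needs_weights
                else ({}, None)
            )
        except ValueError as exc:
            raise ValueError(
                f"weight estimation failed in CV fold {f} (try fewer folds): {exc}"
            ) from exc
        outcomes = tuple(dict.fromkeys(s.outcome for s in specs))
        fitted = {}
        for outcome in outcomes:
            family = "gaussian" if outcome == "continuous" else "binomial"
            y_tr = _outcome_vector(tr_tables, outcome)
            ok = ~np.isnan(y_tr)
            for s in [s for s in specs if s.outcome == outcome]:
                scores = _score_set_for(s, tr_tables, weights)
                if s.estimator == "null":
                    fm = fit_null(y_tr[ok], family)
                elif s.estimator == "ENR":
                    sc = ScoreSet(scores.model_form, scores.predictor_labels,
                                  scores.X[ok].reset_index(drop=True),
                                  scores.study_ids[ok].reset_index(drop=True),
                                  scores.weights_used) if not ok.all() else scores
                    fm = fit_enr(sc, y_tr[ok], family, options.enr, seed=seeds[f + 1])
                else:
                    if not ok.all():
                        scores = ScoreSet(scores.model_form, scores.predictor_labels,
                                          scores.X[ok].reset_index(drop=True),
                                          scores.study_ids[ok].reset_index(drop=True),
                                          scores.weights_used)
                    fm = fit_regression(scores, y_tr[ok], family)
                fm.spec = s
                fitted[(s.model_id, outcome)] = fm
        preds = predict_models(fitted, ho_tables, weights)
        for key, p in preds.items():
            store[key][ho_rows] = p

    for s in specs:
        key = (s.model_id, s.outcome)
        y = pooled[OUTCOME if s.outcome == "continuous" else REMISSION].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        out[key] = (y[keep], store[key][keep])
    return out


@dataclass
class EvaluationReport:
    metrics: pd.DataFrame  # long: model_id, outcome, scope, metric, value
    weights: dict[str, WeightVector]
    network: NetworkModel
    fitted: dict[tuple[int, str], FittedModel]
    calibration: dict[int, CalibrationBins]
    severity: dict[int, SeverityTable]
    correlations: pd.DataFrame
    n_excluded_test: int
    fgl_penalties: tuple[float, float]

    def metric(self, model_id: int, outcome: str, scope: str, name: str) -> float:
        m = self.metrics
        row = m[
            (m.model_id == model_id) & (m.outcome == outcome)
            & (m.scope == scope) & (m.metric == name)
        ]
        if row.empty:
            raise KeyError((model_id, outcome, scope, name))
        return float(row.value.iloc[0])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        pd.concat([w.to_frame() for w in self.weights.values()]).to_csv(
            out / "weights.csv", index=False
        )
        (out / "network.json").write_text(self.network.to_json())
        self.network.edge_list().to_csv(out / "edges.csv", index=False)
        for (mid, outcome), fm in self.fitted.items():
            (out / f"model_{mid}_{outcome}.json").write_text(fm.to_json())
        for mid, cb in self.calibration.items():
            cb.to_frame().to_csv(out / f"calibration_model_{mid}.csv", index=False)
        for mid, st in self.severity.items():
            st.to_frame().to_csv(out / f"severity_model_{mid}.csv", index=False)
        self.correlations.to_csv(out / "prediction_correlations.csv")


def _metric_records(mid: int, outcome: str, ms: MetricSet) -> list[dict]:
    recs = []
    for name in ("r_squared", "rmse", "mae", "auc", "brier"):
        val = getattr(ms, name)
        if val is not None:
            recs.append(
                {"model_id": mid, "outcome": outcome, "scope": ms.scope,
                 "metric": name, "value": val}
            )
    return recs


def run_comparison(config: RunConfig) -> EvaluationReport:
    """Execute the full experiment and return the evaluation report."""
    seeds = _child_seeds(config.seed, 6)

    if config.data_dir is not None:
        tables = read_cohort(config.data_dir)
        logger.info("loaded cohort from %s", config.data_dir)
    else:
        gen = dataclasses.replace(config.generator, seed=seeds[0])
        tables = generate_multi_study(gen)
        if gen.missing_rate > 0:
            tables = inject_missingness(
                tables, gen.missing_rate, config.missingness_scope, seed=seeds[1]
            )
        logger.info("generated %d studies", len(tables))

    train = [t for t in tables if t.role == "train"]
    test = [t for t in tables if t.role == "test"]
    if not train:
        raise ValueError("no training studies in the data source")

    if any(t.data.isna().any().any() for t in train):
        train, report_tr = impute_tables(train, "train", dataclasses.replace(
            config.impute, seed=seeds[2]))
        logger.info("training imputation: %d cells in %d iterations",
                    report_tr.total_imputed, report_tr.iterations)
    if test and any(t.data[list(t.data.columns)].isna().any().any() for t in test):
        test, report_te = impute_tables(test, "test", dataclasses.replace(
            config.impute, seed=seeds[2]))
        logger.info("test imputation: %d cells", report_te.total_imputed)
    n_excluded = 0
    if test:
        test, n_excluded = filter_test_outcomes(test)
        logger.info("excluded %d test patients without outcomes", n_excluded)

    test_hash = _hash_tables(test) if test else ""

    weights, network = estimate_weights(train, config.options, seeds[3])
    fitted = fit_all_models(train, weights, config.options, seeds[4], config.outcomes)

    records: list[dict] = []
    calibration: dict[int, CalibrationBins] = {}
    severity: dict[int, SeverityTable] = {}
    correlations = pd.DataFrame()

    if test:
        preds = predict_models(fitted, test, weights)
        y_cont = _outcome_vector(test, "continuous")
        y_rem = _outcome_vector(test, "remission")
        per_study_slices = {}
        offset = 0
        for t in test:
            per_study_slices[t.study_id] = slice(offset, offset + t.n)
            offset += t.n
        for (mid, outcome), p in preds.items():
            if outcome == "continuous":
                records += _metric_records(mid, outcome, continuous_metrics(y_cont, p))
                for sid, sl in per_study_slices.items():
                    records += _metric_records(
                        mid, outcome,
                        continuous_metrics(y_cont[sl], p[sl], scope=f"per_study:{sid}"),
                    )
            else:
                records += _metric_records(mid, outcome, binary_metrics(y_rem, p))
                for sid, sl in per_study_slices.items():
                    records += _metric_records(
                        mid, outcome,
                        binary_metrics(y_rem[sl], p[sl], scope=f"per_study:{sid}"),
                    )
        if "continuous" in config.outcomes:
            cont = {mid: preds[(mid, "continuous")] for mid in MODEL_IDS
                    if (mid, "continuous") in preds}
            for mid, p in cont.items():
                if mid != 9:
                    calibration[mid] = calibration_bins(y_cont, p, y_rem, config.bin_size)
                    severity[mid] = severity_category_remission(p, y_rem)
            if len(cont) >= 2:
                import warnings as _warnings

                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    correlations = prediction_correlations(cont)

        if _hash_tables(test) != test_hash:
            raise RuntimeError("leakage audit failed: test tables were modified")

    if config.run_internal_cv:
        specs = [model_spec(mid, oc) for oc in config.outcomes
                 for mid in config.internal_cv_models]
        cv = cross_validated_predictions(
            train, specs, folds=config.internal_cv_folds, seed=seeds[5],
            options=config.options,
        )
        for (mid, outcome), (y, p) in cv.items():
            ms = (continuous_metrics(y, p, scope="internal_cv")
                  if outcome == "continuous"
                  else binary_metrics(y, p, scope="internal_cv"))
            records += _metric_records(mid, outcome, ms)

    metrics = pd.DataFrame(records, columns=["model_id", "outcome", "scope",
                                             "metric", "value"])
    return EvaluationReport(
        metrics=metrics,
        weights=weights,
        network=network,
        fitted=fitted,
        calibration=calibration,
        severity=severity,
        correlations=correlations,
        n_excluded_test=n_excluded,
        fgl_penalties=(network.lambda1, network.lambda2),
    )
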