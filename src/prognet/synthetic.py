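"""Synthetic multi-study cohorts with a latent-severity + residual-network structure.

Stands in for individual patient data from several randomised controlled
trials of depression treatment in primary care. Each study draws a latent
severity factor per patient; the 32 baseline variables are thresholded or
rescaled Gaussian functions of that factor plus residual noise whose
precision structure carries configurable item-item partial correlations.
The follow-up depressive total is a linear function of the true latent
severity and the auxiliary psychosocial totals plus Gaussian noise.
Between-study heterogeneity enters as study-specific shifts of the latent
factor mean; test studies can additionally be shifted to emulate a more
severe external-validation sample.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .variables import (
    ANX_SUBSCALES,
    AUX_TOTALS,
    BASELINE_VARS,
    BDI_ITEMS,
    OUTCOME,
    PATIENT_ID,
    REMISSION,
    REMISSION_THRESHOLD,
    STUDY_ID,
    VALUE_RANGES,
)


class ConfigError(ValueError):
    """Raised when a GeneratorConfig field is invalid; names the field."""


#: Default marginal category probabilities for the ordinal items.
BDI_CATEGORY_PROBS = (0.35, 0.35, 0.20, 0.10)
ANX_CATEGORY_PROBS = (0.40, 0.25, 0.15, 0.12, 0.08)

#: Linear centre/scale used to map a unit-variance latent onto each
#: auxiliary total before rounding and clipping to its range.
AUX_LINEAR = {
    "social_support": (14.0, 4.0),
    "life_events": (3.0, 2.0),
    "alcohol": (4.0, 3.0),
}


def _default_loadings() -> list[float]:
    # Depressive items load strongest on the severity factor, anxiety
    # subscales moderately, auxiliary totals weakly (support protective).
    rng = np.random.default_rng(20230117)
    bdi = np.round(rng.uniform(0.55, 0.80, len(BDI_ITEMS)), 2)
    anx = np.round(rng.uniform(0.35, 0.55, len(ANX_SUBSCALES)), 2)
    aux = np.array([-0.35, 0.30, 0.15])
    return np.concatenate([bdi, anx, aux]).tolist()


def _default_residual_network() -> np.ndarray:
    """Sparse residual partial correlations between related symptom pairs."""
    p = len(BASELINE_VARS)
    idx = {v: i for i, v in enumerate(BASELINE_VARS)}
    net = np.zeros((p, p))
    pairs = [
        ("bdi_15", "bdi_16", 0.20),  # loss of energy / sleep change
        ("bdi_16", "bdi_20", 0.20),  # sleep change / fatigue
        ("bdi_18", "bdi_19", 0.20),  # appetite / concentration
        ("bdi_02", "bdi_09", 0.15),  # pessimism / suicidal thoughts
        ("anx_worry", "anx_generalised", 0.25),
        ("anx_phobic", "anx_panic", 0.20),
    ]
    for a, b, w in pairs:
        net[idx[a], idx[b]] = net[idx[b], idx[a]] = w
    return net


@dataclass
class GeneratorConfig:
    """Configuration for the multi-study generator.

    ``n_per_study`` lists sizes for training studies first, then test
    studies. ``outcome_coefficients`` is ``(intercept, latent_severity,
    social_support, life_events, alcohol)`` on the follow-up-total scale.
    """

    n_studies_train: int = 3
    n_studies_test: int = 3
    n_per_study: list[int] = field(default_factory=lambda: [575] * 3 + [300] * 3)
    latent_loadings: list[float] = field(default_factory=_default_loadings)
    residual_network: np.ndarray | None = field(default_factory=_default_residual_network)
    study_mean_shift_sd: float = 0.15
    test_severity_shift: float = 0.55
    outcome_coefficients: list[float] = field(
        default_factory=lambda: [12.5, 6.0, -0.25, 0.5, 0.15]
    )
    outcome_noise_sd: float = 11.0
    missing_rate: float = 0.008
    seed: int = 0

    def validate(self) -> None:
        p = len(BASELINE_VARS)
        n_total = self.n_studies_train + self.n_studies_test
        if self.n_studies_train < 0 or n_total < 1:
            raise ConfigError("n_studies_train/n_studies_test: need at least one study")
        if len(self.n_per_study) != n_total:
            raise ConfigError(
                f"n_per_study: expected {n_total} entries, got {len(self.n_per_study)}"
            )
        if any(n < 1 for n in self.n_per_study):
            raise ConfigError("n_per_study: all sizes must be >= 1")
        lam = np.asarray(self.latent_loadings, dtype=float)
        if lam.shape != (p,):
            raise ConfigError(f"latent_loadings: expected length {p}, got {lam.shape}")
        if np.any(lam**2 >= 1.0):
            raise ConfigError("latent_loadings: |loading| must be < 1")
        if self.residual_network is not None:
            net = np.asarray(self.residual_network, dtype=float)
            if net.shape != (p, p):
                raise ConfigError(f"residual_network: expected shape ({p},{p})")
            if not np.allclose(net, net.T):
                raise ConfigError("residual_network: must be symmetric")
            if np.any(np.diag(net) != 0):
                raise ConfigError("residual_network: diagonal must be zero")
            if np.min(np.linalg.eigvalsh(np.eye(p) - net)) <= 1e-10:
                raise ConfigError("residual_network: implied precision not positive definite")
        if len(self.outcome_coefficients) != 5:
            raise ConfigError("outcome_coefficients: expected 5 values "
                              "(intercept, latent, social_support, life_events, alcohol)")
        if self.outcome_noise_sd < 0:
            raise ConfigError("outcome_noise_sd: must be >= 0")
        if not 0.0 <= self.missing_rate < 0.30:
            raise ConfigError("missing_rate: must lie in [0, 0.30)")
        if self.study_mean_shift_sd < 0:
            raise ConfigError("study_mean_shift_sd: must be >= 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["residual_network"] is not None:
            d["residual_network"] = np.asarray(d["residual_network"]).tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        d = json.loads(text)
        if d.get("residual_network") is not None:
            d["residual_network"] = np.asarray(d["residual_network"], dtype=float)
        return cls(**d)


def default_cohort_config(seed: int = 0) -> GeneratorConfig:
    """The default fixture: 3 training + 3 test studies, n ~ 575/300 per
    study, test studies shifted toward higher severity (follow-up totals
    roughly 3.5 points higher on average)."""
    return GeneratorConfig(seed=seed)


@dataclass
class StudyTable:
    """One study's patient-level table (baseline variables + follow-up)."""

    study_id: str
    role: str  # "train" | "test"
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ("train", "test"):
            raise ValueError(f"role must be 'train' or 'test', got {self.role!r}")

    def copy(self) -> "StudyTable":
        return StudyTable(self.study_id, self.role, self.data.copy())

    @property
    def n(self) -> int:
        return len(self.data)

    def validate(self) -> None:
        df = self.data
        for col in BASELINE_VARS + [OUTCOME]:
            lo, hi = VALUE_RANGES[col]
            vals = df[col].dropna()
            if len(vals) and (vals.min() < lo or vals.max() > hi):
                raise ValueError(f"{self.study_id}: {col} outside [{lo}, {hi}]")
        present = df[OUTCOME].notna()
        expected = (df.loc[present, OUTCOME] <= REMISSION_THRESHOLD).astype(float)
        if not np.array_equal(expected.to_numpy(), df.loc[present, REMISSION].to_numpy()):
            raise ValueError(f"{self.study_id}: remission flag inconsistent with threshold")


def _latent_covariance(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return (loadings, cholesky of the residual covariance)."""
    p = len(BASELINE_VARS)
    lam = np.asarray(config.latent_loadings, dtype=float)
    if config.residual_network is None:
        resid_corr = np.eye(p)
    else:
        omega = np.eye(p) - np.asarray(config.residual_network, dtype=float)
        cov = np.linalg.inv(omega)
        d = np.sqrt(np.diag(cov))
        resid_corr = cov / np.outer(d, d)
    sd_e = np.sqrt(1.0 - lam**2)
    resid_cov = resid_corr * np.outer(sd_e, sd_e)
    return lam, np.linalg.cholesky(resid_cov)


def _ordinal_cutpoints(probs: tuple[float, ...]) -> np.ndarray:
    return stats.norm.ppf(np.cumsum(probs[:-1]))


def generate_multi_study(config: GeneratorConfig) -> list[StudyTable]:
    """Generate all training and test study tables.

    Deterministic given ``config`` (including its seed). Items are produced
    by thresholding latent Gaussians whose covariance combines the single
    severity factor and the residual network; study mean shifts move the
    factor mean. The outcome is the linear predictor plus Gaussian noise,
    rounded and clipped to 0..63.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lam, chol = _latent_covariance(config)
    bdi_cuts = _ordinal_cutpoints(BDI_CATEGORY_PROBS)
    anx_cuts = _ordinal_cutpoints(ANX_CATEGORY_PROBS)
    c0, c_f, c_ss, c_le, c_alc = (float(c) for c in config.outcome_coefficients)

    tables: list[StudyTable] = []
    n_total = config.n_studies_train + config.n_studies_test
    for s in range(n_total):
        role = "train" if s < config.n_studies_train else "test"
        n = config.n_per_study[s]
        shift = rng.normal(0.0, config.study_mean_shift_sd)
        if role == "test":
            shift += config.test_severity_shift
        f = shift + rng.standard_normal(n)
        e = rng.standard_normal((n, len(BASELINE_VARS))) @ chol.T
        x = f[:, None] * lam[None, :] + e

        df = pd.DataFrame(index=range(n))
        df[STUDY_ID] = f"study_{s + 1:02d}"
        df[PATIENT_ID] = [f"study_{s + 1:02d}_p{i + 1:04d}" for i in range(n)]
        for j, col in enumerate(BASELINE_VARS):
            if col in BDI_ITEMS:
                df[col] = np.searchsorted(bdi_cuts, x[:, j])
            elif col in ANX_SUBSCALES:
                df[col] = np.searchsorted(anx_cuts, x[:, j])
            else:
                centre, scale = AUX_LINEAR[col]
                lo, hi = VALUE_RANGES[col]
                df[col] = np.clip(np.round(centre + scale * x[:, j]), lo, hi).astype(int)

        linpred = (
            c0
            + c_f * f
            + c_ss * df["social_support"].to_numpy()
            + c_le * df["life_events"].to_numpy()
            + c_alc * df["alcohol"].to_numpy()
        )
        y = linpred + rng.normal(0.0, config.outcome_noise_sd, n)
        df[OUTCOME] = np.clip(np.round(y), 0, 63).astype(int)
        df[REMISSION] = (df[OUTCOME] <= REMISSION_THRESHOLD).astype(float)
        tables.append(StudyTable(df[STUDY_ID].iloc[0], role, df))
    return tables


def inject_missingness(
    tables: list[StudyTable],
    missing_rate: float,
    scope: str = "baseline_only",
    seed: int = 0,
) -> list[StudyTable]:
    """Set cells missing completely at random at the given per-cell rate.

    ``scope`` is ``baseline_only`` (test-study outcomes are never masked) or
    ``baseline_and_training_outcome`` (training outcomes also eligible).
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    if scope not in ("baseline_only", "baseline_and_training_outcome"):
        raise ValueError(f"unknown scope: {scope!r}")
    rng = np.random.default_rng(seed)
    out = []
    for t in tables:
        df = t.data.copy()
        cols = list(BASELINE_VARS)
        if scope == "baseline_and_training_outcome" and t.role == "train":
            cols.append(OUTCOME)
        if missing_rate > 0:
            for col in cols:
                mask = rng.random(len(df)) < missing_rate
                df[col] = df[col].astype(float).mask(mask)
            df[REMISSION] = df[REMISSION].astype(float).mask(df[OUTCOME].isna())
        out.append(StudyTable(t.study_id, t.role, df))
    return out


# ---------------------------------------------------------------------------
# CSV round trip. One CSV per study with a fixed header; missing cells are
# empty fields; a JSON sidecar stores the generator config and study roles.

CSV_COLUMNS = [STUDY_ID, PATIENT_ID] + BASELINE_VARS + [OUTCOME, REMISSION]


def write_study_csv(table: StudyTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_study_csv(path: str | Path, role: str) -> StudyTable:
    df = pd.read_csv(path)
    missing_cols = set(CSV_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    return StudyTable(str(df[STUDY_ID].iloc[0]), role, df[CSV_COLUMNS])


def write_cohort(
    tables: list[StudyTable], out_dir: str | Path, config: GeneratorConfig | None = None
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"studies": []}
    for t in tables:
        fname = f"{t.study_id}.csv"
        write_study_csv(t, out_dir / fname)
        manifest["studies"].append({"file": fname, "study_id": t.study_id, "role": t.role})
    (out_dir / "cohort.json").write_text(json.dumps(manifest, indent=2))
    if config is not None:
        (out_dir / "generator_config.json").write_text(config.to_json())


def read_cohort(in_dir: str | Path) -> list[StudyTable]:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "cohort.json").read_text())
    return [read_study_csv(in_dir / s["file"], s["role"]) for s in manifest["studies"]]
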