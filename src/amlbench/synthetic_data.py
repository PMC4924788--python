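"""Synthetic AML-like cohorts and simulated predictors.

This module generates patient cohorts with the statistical structure a
proteomics-based prognosis challenge assumes — a binary response-to-therapy
outcome (complete remission vs. resistant to induction therapy), plus
right-censored remission-duration and overall-survival times in weeks —
together with a population of simulated predictors of tunable skill, so the
whole assessment pipeline (scoring, leaderboards, rank stability, feature
importance) can be exercised without access to any real patient data.

The outcome model is a shared latent-risk construction:

* a risk score ``z = w . x + eps`` combines a handful of weighted features
  (protein levels and clinical covariates) with Gaussian noise;
* response to therapy follows a latent-utility logistic link:
  a patient is Resistant iff ``z + eta > c`` with ``eta`` standard logistic,
  where the intercept ``c`` is solved numerically so the expected complete
  remission (CR) fraction equals the configured prevalence;
* remission duration and survival are Weibull times whose scale shrinks with
  ``z`` (higher risk, shorter times), censored by independent exponential
  times calibrated to the configured censoring rates.

Protein levels are drawn from a low-rank multivariate normal and
column-standardised, mimicking normalised reverse-phase protein array (RPPA)
data where a value below 0 means "low".  One designated protein (default
``PIK3CA``) carries a negative outcome weight so resistant patients are
biased toward low levels of it — the association the importance analysis is
expected to rediscover.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "PredictorConfig",
    "PredictionSet",
    "ChallengeBundle",
    "SUBCHALLENGES",
    "generate_cohort",
    "simulate_predictor",
    "LinearPredictor",
    "generate_challenge",
    "substream",
]

SUBCHALLENGES = ("SC1", "SC2", "SC3")

#: Named proteins at the head of the panel; the remainder are Protein_###.
_NAMED_PROTEINS = ("PIK3CA", "NPM1", "GSK3AB", "PTEN")

#: Levels used for the named categorical clinical covariates.
_CHEMO_LEVELS = ("Standard", "HighDose", "FLU-HDAC", "Demethylating")
_CHEMO_PROBS = (0.45, 0.25, 0.2, 0.1)


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent RNG substream derived from a root seed.

    The stream key is a CRC-32 of the name, so adding or reordering streams
    never perturbs the draws of an existing one.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the challenge cohort scale: 291 patients, a 231-protein
    RPPA panel, ~40 clinical covariates and a ~71%/29% CR/Resistant split.
    """

    n_patients: int = 291
    n_proteins: int = 231
    n_clinical: int = 40
    cr_prevalence: float = 0.71
    latent_dim: int = 5
    outcome_effect_weights: Mapping[str, float] | None = None
    rd_censor_rate: float = 0.25
    os_censor_rate: float = 0.25
    baseline_hazard_scale: float = 60.0  # weeks
    designated_protein: str = "PIK3CA"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cr_prevalence < 1.0:
            raise ConfigurationError(
                f"cr_prevalence must lie strictly in (0, 1); got {self.cr_prevalence}"
            )
        for name in ("rd_censor_rate", "os_censor_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]; got {rate}")
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be at least 1")
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be at least 2")
        if self.n_clinical < 3:
            raise ConfigurationError("n_clinical must cover the 3 named covariates")
        if self.baseline_hazard_scale <= 0:
            raise ConfigurationError("baseline_hazard_scale must be positive")

    def protein_names(self) -> list[str]:
        named = list(_NAMED_PROTEINS[: self.n_proteins])
        fillers = [
            f"Protein_{i:03d}" for i in range(len(named) + 1, self.n_proteins + 1)
        ]
        return named + fillers

    def clinical_names(self) -> list[str]:
        names = ["Age", "Chemotherapy", "AHD"]
        names += [f"Clinical_{i:02d}" for i in range(4, self.n_clinical + 1)]
        return names

    def default_weights(self) -> dict[str, float]:
        """Outcome weights used when ``outcome_effect_weights`` is None.

        The designated protein gets a negative weight (low level -> high
        risk -> Resistant); age and antecedent haematological disorder (AHD)
        increase risk.
        """
        weights = {
            self.designated_protein: -1.5,
            "Age": 0.6,
            "AHD": 0.5,
        }
        for name, w in (("NPM1", -0.5), ("GSK3AB", -0.35), ("PTEN", -0.3)):
            if name in self.protein_names() and name != self.designated_protein:
                weights[name] = w
        return weights

    def resolved_weights(self) -> dict[str, float]:
        if self.outcome_effect_weights is not None:
            return dict(self.outcome_effect_weights)
        return self.default_weights()


# ---------------------------------------------------------------------------
# cohort containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTruth:
    """Hidden generative state backing a synthetic cohort.

    ``utility`` is the full latent utility (risk score plus the logistic
    disturbance) that deterministically separates CR from Resistant; the
    true, uncensored event times are kept for every patient, including the
    remission times of patients who never entered remission.
    """

    risk: pd.Series  # latent risk score z per patient
    utility: pd.Series  # z + logistic noise; label = Resistant iff > intercept
    intercept: float
    rd_true_weeks: pd.Series  # uncensored remission-duration times
    os_true_weeks: pd.Series  # uncensored survival times

    def subset(self, ids: Sequence) -> "CohortTruth":
        idx = pd.Index(ids)
        return CohortTruth(
            risk=self.risk.loc[idx],
            utility=self.utility.loc[idx],
            intercept=self.intercept,
            rd_true_weeks=self.rd_true_weeks.loc[idx],
            os_true_weeks=self.os_true_weeks.loc[idx],
        )


@dataclass
class Cohort:
    """A synthetic (or loaded) patient cohort.

    ``data`` is indexed by ``patient_id`` and holds the clinical covariates,
    the centred protein levels and the outcome columns ``rt_label``
    (CR/Resistant), ``rd_weeks``/``rd_event`` (NaN/empty for Resistant
    patients, for whom remission duration is undefined) and
    ``os_weeks``/``os_event``.
    """

    data: pd.DataFrame
    protein_names: list[str]
    clinical_names: list[str]
    config: CohortConfig | None = None
    truth: CohortTruth | None = None

    OUTCOME_COLUMNS = ("rt_label", "rd_weeks", "rd_event", "os_weeks", "os_event")

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("patient ids must be unique")
        proteins = self.data[self.protein_names]
        if not np.isfinite(proteins.to_numpy(dtype=float)).all():
            raise ValueError("protein columns must be finite")

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return self.clinical_names + self.protein_names

    def features(self) -> pd.DataFrame:
        """Covariate table (clinical + proteins) without outcome columns."""
        return self.data[self.feature_names]

    def outcomes(self) -> pd.DataFrame:
        """Outcome table: the truth against which predictions are scored."""
        return self.data[list(self.OUTCOME_COLUMNS)]

    def subset(self, ids: Sequence) -> "Cohort":
        idx = pd.Index(ids)
        return Cohort(
            data=self.data.loc[idx],
            protein_names=self.protein_names,
            clinical_names=self.clinical_names,
            config=self.config,
            truth=self.truth.subset(idx) if self.truth is not None else None,
        )


@dataclass(frozen=True)
class PredictorConfig:
    """A simulated participant: a skill level and optional feature reliance.

    ``skill`` in [0, 1] mixes the true signal with independent noise;
    ``feature_weights`` (used by :class:`LinearPredictor`) names the cohort
    features the predictor reads, standing in for a trained model's learned
    dependence on them.
    """

    team_id: str
    skill: float = 0.5
    feature_weights: Mapping[str, float] | None = None
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise ConfigurationError(f"skill must lie in [0, 1]; got {self.skill}")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be nonnegative")


@dataclass
class PredictionSet:
    """One team's predictions for one sub-challenge.

    SC1 carries a per-patient confidence (probability of CR); SC2/SC3 carry
    predicted weeks plus a confidence in [0, 1] that the scoring ignores.
    """

    team_id: str
    subchallenge: str
    frame: pd.DataFrame  # index patient_id; columns confidence[, predicted_weeks]

    def __post_init__(self) -> None:
        if self.subchallenge not in SUBCHALLENGES:
            raise ValueError(f"unknown sub-challenge {self.subchallenge!r}")
        if not self.frame.index.is_unique:
            raise ValueError(f"duplicate patient ids in predictions of {self.team_id}")
        conf = self.frame["confidence"].to_numpy(dtype=float)
        if ((conf < 0) | (conf > 1)).any() or not np.isfinite(conf).all():
            raise ValueError(f"confidences of {self.team_id} must lie in [0, 1]")
        if self.subchallenge in ("SC2", "SC3"):
            weeks = self.frame["predicted_weeks"].to_numpy(dtype=float)
            if (weeks <= 0).any() or not np.isfinite(weeks).all():
                raise ValueError(f"predicted weeks of {self.team_id} must be positive")

    @property
    def patient_ids(self) -> pd.Index:
        return self.frame.index

    def covers(self, ids: Sequence) -> bool:
        return pd.Index(ids).isin(self.frame.index).all()

    def confidences(self, ids: Sequence) -> np.ndarray:
        return self.frame["confidence"].loc[pd.Index(ids)].to_numpy(dtype=float)

    def weeks(self, ids: Sequence) -> np.ndarray:
        return self.frame["predicted_weeks"].loc[pd.Index(ids)].to_numpy(dtype=float)


@dataclass
class ChallengeBundle:
    """Everything one simulated challenge round produces."""

    train: Cohort
    test: Cohort
    truth: pd.DataFrame  # outcome table of the test cohort
    predictions: dict[tuple[str, str], PredictionSet]  # (team_id, SC) -> set

    def sets_for(self, subchallenge: str) -> list[PredictionSet]:
        return [p for (_, sc), p in self.predictions.items() if sc == subchallenge]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _feature_signal(values: pd.Series) -> np.ndarray:
    """Standardised numeric signal for a (possibly categorical) column."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(values.astype(str)))
        codes = values.astype(str).map({lv: i for i, lv in enumerate(levels)})
        return _standardize(codes.to_numpy(dtype=float))
    return _standardize(values.to_numpy(dtype=float))


def _solve_intercept(z: np.ndarray, cr_prevalence: float) -> float:
    """Bisect the logistic intercept so mean P(Resistant | z) = 1 - prevalence."""
    target = 1.0 - cr_prevalence

    def mean_resistant(c: float) -> float:
        # P(Resistant | z) = sigma(z - c)
        return float(np.mean(1.0 / (1.0 + np.exp(-(z - c)))))

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_resistant(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _solve_censor_scale(times: np.ndarray, rate: float) -> float:
    """Exponential-censoring mean so the expected censored fraction = rate."""
    if rate <= 0:
        return math.inf

    def frac_censored(mu: float) -> float:
        # P(C < T_i | T_i) for C ~ Exp(mean mu)
        return float(np.mean(1.0 - np.exp(-times / mu)))

    lo, hi = 1e-6, 1e9
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if frac_censored(mid) > rate:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _generate_proteins(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Low-rank correlated Gaussian panel, column-standardised (RPPA-like)."""
    n, p, k = config.n_patients, config.n_proteins, max(config.latent_dim, 1)
    loadings = rng.normal(size=(k, p)) / math.sqrt(k)
    latent = rng.normal(size=(n, k))
    noise = rng.normal(scale=0.6, size=(n, p))
    raw = latent @ loadings + noise
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    return pd.DataFrame(raw, columns=config.protein_names())


def _generate_clinical(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    cols: dict[str, np.ndarray] = {}
    cols["Age"] = np.clip(rng.normal(57.0, 14.0, size=n), 18.0, 90.0).round(1)
    cols["Chemotherapy"] = rng.choice(_CHEMO_LEVELS, size=n, p=_CHEMO_PROBS)
    cols["AHD"] = rng.choice(["Yes", "No"], size=n, p=[0.22, 0.78])
    # Filler covariates alternate continuous lab-style values and small
    # categorical factors, standing in for the unnamed clinical indicators.
    for i, name in enumerate(config.clinical_names()[3:], start=4):
        if i % 3 == 0:
            k = 2 + (i % 3)
            cols[name] = rng.choice([f"L{j}" for j in range(k)], size=n)
        else:
            cols[name] = rng.normal(0.0, 1.0, size=n).round(4)
    return pd.DataFrame(cols)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a synthetic AML-like cohort.

    Deterministic given ``config.seed``.  The returned cohort carries its
    hidden :class:`CohortTruth` so simulated predictors can be built from it.
    """
    weights = config.resolved_weights()
    proteins = _generate_proteins(config, substream(config.seed, "proteins"))
    clinical = _generate_clinical(config, substream(config.seed, "clinical"))
    features = pd.concat([clinical, proteins], axis=1)

    unknown = [f for f in weights if f not in features.columns]
    if unknown:
        raise ConfigurationError(f"outcome weights name unknown features: {unknown}")

    rng = substream(config.seed, "outcomes")
    z = np.zeros(config.n_patients)
    for name, w in weights.items():
        z += w * _feature_signal(features[name])
    z += rng.normal(scale=0.5, size=config.n_patients)

    intercept = _solve_intercept(z, config.cr_prevalence)
    eta = rng.logistic(size=config.n_patients)
    utility = z + eta
    resistant = utility > intercept
    rt_label = np.where(resistant, "Resistant", "CR")

    # Weibull event times with scale shrinking in risk; shape > 1 gives an
    # ageing hazard typical of relapse/mortality after induction.
    shape = 1.3
    gamma = 0.5
    z_c = z - z.mean()
    os_scale = config.baseline_hazard_scale * np.exp(-gamma * z_c)
    rd_scale = 0.8 * config.baseline_hazard_scale * np.exp(-gamma * z_c)
    os_true = os_scale * rng.weibull(shape, size=config.n_patients)
    rd_true = rd_scale * rng.weibull(shape, size=config.n_patients)
    os_true = np.maximum(os_true, 0.1)
    rd_true = np.maximum(rd_true, 0.1)

    os_cens = _draw_censoring(os_true, config.os_censor_rate, rng)
    os_weeks = np.minimum(os_true, os_cens).round(1)
    os_event = np.where(os_true <= os_cens, "deceased", "censored")

    cr_mask = ~resistant
    rd_weeks = np.full(config.n_patients, np.nan)
    rd_event = np.full(config.n_patients, "", dtype=object)
    if cr_mask.any():
        rd_cens = _draw_censoring(rd_true[cr_mask], config.rd_censor_rate, rng)
        rd_obs = np.minimum(rd_true[cr_mask], rd_cens).round(1)
        rd_weeks[cr_mask] = rd_obs
        rd_event[cr_mask] = np.where(
            rd_true[cr_mask] <= rd_cens, "relapsed", "censored"
        )

    ids = pd.Index([f"P{i:04d}" for i in range(1, config.n_patients + 1)], name="patient_id")
    data = features.copy()
    data.index = ids
    data["rt_label"] = rt_label
    data["rd_weeks"] = rd_weeks
    data["rd_event"] = rd_event
    data["os_weeks"] = os_weeks
    data["os_event"] = os_event

    truth = CohortTruth(
        risk=pd.Series(z, index=ids),
        utility=pd.Series(utility, index=ids),
        intercept=intercept,
        rd_true_weeks=pd.Series(rd_true, index=ids),
        os_true_weeks=pd.Series(os_true, index=ids),
    )
    return Cohort(
        data=data,
        protein_names=config.protein_names(),
        clinical_names=config.clinical_names(),
        config=config,
        truth=truth,
    )


def _draw_censoring(times: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return np.full_like(times, np.inf)
    mu = _solve_censor_scale(times, rate)
    return rng.exponential(scale=mu, size=times.shape)


# ---------------------------------------------------------------------------
# simulated predictors
# ---------------------------------------------------------------------------


def _skill_mix(
    signal: np.ndarray, skill: float, noise_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Mix a standardised true signal with independent Gaussian noise.

    skill = 1 reproduces the signal exactly; skill = 0 is pure noise.
    """
    eps = rng.normal(scale=noise_scale if noise_scale > 0 else 1.0, size=signal.shape)
    if noise_scale == 0:
        eps = np.zeros_like(signal)
    return skill * signal + math.sqrt(1.0 - skill * skill) * eps


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _rank_preserving_weeks(mixed: np.ndarray, true_weeks: np.ndarray) -> np.ndarray:
    """Map a mixed score onto the empirical time distribution, preserving ranks."""
    order = np.argsort(np.argsort(mixed, kind="stable"), kind="stable")
    return np.sort(true_weeks)[order]


def simulate_predictor(
    cohort: Cohort,
    truth: CohortTruth,
    config: PredictorConfig,
    subchallenge: str,
) -> PredictionSet:
    """Simulate one team's submission for one sub-challenge.

    The prediction is a skill-weighted mixture of the true latent signal and
    noise: for SC1 the signal is the (standardised, negated) latent utility,
    so a skill-1 predictor ranks every CR patient above every Resistant
    patient; for SC2/SC3 the predicted weeks are a rank-preserving noisy
    transform of the true uncensored times.  Deterministic given
    ``config.seed``.
    """
    if subchallenge not in SUBCHALLENGES:
        raise ValueError(f"unknown sub-challenge {subchallenge!r}")
    rng = substream(config.seed, f"predictor:{config.team_id}:{subchallenge}")
    ids = cohort.patient_ids

    if subchallenge == "SC1":
        signal = -_standardize(truth.utility.loc[ids].to_numpy())
        mixed = _skill_mix(signal, config.skill, config.noise_scale, rng)
        frame = pd.DataFrame({"confidence": _logistic(mixed)}, index=ids)
        return PredictionSet(config.team_id, subchallenge, frame)

    true_weeks = (
        truth.rd_true_weeks if subchallenge == "SC2" else truth.os_true_weeks
    ).loc[ids].to_numpy()
    signal = _standardize(np.log(true_weeks))
    mixed = _skill_mix(signal, config.skill, config.noise_scale, rng)
    weeks = _rank_preserving_weeks(mixed, true_weeks)
    frame = pd.DataFrame(
        {
            "confidence": _logistic(_standardize(mixed)),
            "predicted_weeks": np.maximum(weeks, 1e-3),
        },
        index=ids,
    )
    return PredictionSet(config.team_id, subchallenge, frame)


class LinearPredictor:
    """A feature-reading predictor handle for importance analysis.

    Wraps a sparse weight vector over named cohort features into an
    evaluable model: ``predict(table)`` standardises each weighted column of
    the given feature table (categoricals via sorted-level codes) and mixes
    the weighted sum with per-patient noise according to ``skill``.  The
    noise stream is keyed to a hash of the input table, so the handle is a
    deterministic function of the table while its intrinsic noise still
    re-draws whenever any cell changes — a feature-free predictor therefore
    scores above and below its baseline with equal frequency under
    scrambling, instead of tying every repetition.
    """

    def __init__(self, config: PredictorConfig, subchallenge: str = "SC1") -> None:
        if config.feature_weights is None:
            raise ConfigurationError("LinearPredictor requires feature_weights")
        if subchallenge not in SUBCHALLENGES:
            raise ValueError(f"unknown sub-challenge {subchallenge!r}")
        self.config = config
        self.subchallenge = subchallenge

    @property
    def team_id(self) -> str:
        return self.config.team_id

    def predict(self, table: pd.DataFrame) -> PredictionSet:
        cfg = self.config
        missing = [f for f in cfg.feature_weights if f not in table.columns]
        if missing:
            raise KeyError(f"features absent from table: {missing}")
        raw = np.zeros(len(table))
        for name, w in cfg.feature_weights.items():
            raw += w * _feature_signal(table[name])
        signal = _standardize(raw) if raw.std() > 0 else raw
        # Noise keyed to the table content: identical tables give identical
        # predictions; any changed cell re-draws the noise stream.
        digest = zlib.crc32(
            pd.util.hash_pandas_object(table, index=True).to_numpy().tobytes()
        )
        key = zlib.crc32(f"linear:{cfg.team_id}:{self.subchallenge}".encode())
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, key, digest])
        )
        mixed = _skill_mix(signal, cfg.skill, cfg.noise_scale, rng)
        if self.subchallenge == "SC1":
            frame = pd.DataFrame({"confidence": _logistic(-mixed)}, index=table.index)
        else:
            weeks = 60.0 * np.exp(-0.5 * mixed)
            frame = pd.DataFrame(
                {"confidence": _logistic(-mixed), "predicted_weeks": weeks},
                index=table.index,
            )
        return PredictionSet(cfg.team_id, self.subchallenge, frame)

    __call__ = predict


def generate_challenge(
    cohort_config: CohortConfig,
    predictor_configs: Sequence[PredictorConfig],
    train_size: int = 191,
    test_size: int = 100,
    subchallenges: Sequence[str] = SUBCHALLENGES,
    partition_config=None,
) -> ChallengeBundle:
    """Generate a full challenge round: cohort, matched split, predictions.

    The train/test partition is produced by the genetic-algorithm splitter
    (:func:`amlbench.partition_ga.ga_partition`) so both sides have
    equivalent covariate and outcome distributions, as in the original
    challenge design.
    """
    from .partition_ga import PartitionConfig, ga_partition

    if train_size + test_size != cohort_config.n_patients:
        raise ConfigurationError(
            f"train_size + test_size must equal n_patients "
            f"({train_size} + {test_size} != {cohort_config.n_patients})"
        )
    cohort = generate_cohort(cohort_config)
    if partition_config is None:
        partition_config = PartitionConfig(
            train_size=train_size,
            test_size=test_size,
            seed=cohort_config.seed,
        )
    elif (partition_config.train_size, partition_config.test_size) != (
        train_size,
        test_size,
    ):
        partition_config = replace(
            partition_config, train_size=train_size, test_size=test_size
        )
    partition = ga_partition(cohort, partition_config)
    train_ids = cohort.patient_ids[partition.membership == 1]
    test_ids = cohort.patient_ids[partition.membership == 0]
    train = cohort.subset(train_ids)
    test = cohort.subset(test_ids)

    predictions: dict[tuple[str, str], PredictionSet] = {}
    for pc in predictor_configs:
        for sc in subchallenges:
            predictions[(pc.team_id, sc)] = simulate_predictor(
                test, test.truth, pc, sc
            )
    return ChallengeBundle(
        train=train, test=test, truth=test.outcomes(), predictions=predictions
    )
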