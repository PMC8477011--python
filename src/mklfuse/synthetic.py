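"""Synthetic multimodal cohort generator.

Emulates the statistical structure of tabulated, image-derived feature
tables from a matched case/control neurodevelopmental study: three
modalities (structural MRI morphometry/intensity, DTI diffusivities,
resting-state functional connectivity) measured on the same subjects,
acquired on several scanners (batches) that impose additive and
multiplicative effects, with a sparse set of group-separating features
per modality embedded in block-correlated Gaussian noise.

Feature model for subject i, modality m, feature f::

    x_if = delta * 1[i is case] * 1[f informative]
         + age_slope * z_age_i
         + scale(b_i, f) * eps_if                (block-correlated N(0,1))
         + shift(b_i, f)

where ``shift(b,f) = batch_shift * u_bf`` and ``scale(b,f) =
batch_scale ** v_bf`` with fixed per-(batch, feature) draws
``u_bf ~ N(0,1)``, ``v_bf ~ U(-1,1)``.  Batches are assigned
independently of the label, so harmonization must not erase the planted
group effect.  Labels are coded +1 (case) / -1 (control).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("sMRI", "DTI", "rsfMRI")

#: Candidate-feature pool sizes of the tabulated image measures.
DEFAULT_DIMS = {"sMRI": 1184, "DTI": 1182, "rsfMRI": 338}

#: Informative-feature counts, chosen near the per-modality sizes of the
#: relevant subsets an all-relevant selector finds on the real tables.
DEFAULT_INFORMATIVE = {"sMRI": 5, "DTI": 10, "rsfMRI": 13}

#: Matched race composition per group (White/Hispanic/Black/Asian/Other).
RACE_COUNTS = {"White": 80, "Hispanic": 13, "Black": 10, "Asian": 12, "Other": 1}


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults mirror the matched cohort the pipeline is designed for:
    116 cases / 116 controls, 45 female and 71 male per group, age about
    118.7 +/- 7.7 months, race composition matched exactly between groups.
    """

    n_case: int = 116
    n_control: int = 116
    n_female_per_group: int = 45
    modality_dims: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DIMS))
    n_informative: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INFORMATIVE)
    )
    effect_size: float = 1.0  # standardized mean difference delta
    block_corr: float = 0.3  # within-block correlation rho
    block_size: int = 10
    n_batches: int = 3
    batch_shift: float = 0.3
    batch_scale: float = 1.1
    age_mean_case: float = 118.4  # months
    age_mean_control: float = 118.9
    age_sd: float = 7.7
    age_slope: float = 0.1  # feature change per SD of age, all features
    confound_batch_with_label: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 0 or self.n_control < 0:
            raise ValueError("group sizes must be non-negative")
        if not 0.0 <= self.block_corr < 1.0:
            raise ValueError("block_corr must lie in [0, 1)")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        for m, d in self.modality_dims.items():
            if d < 0:
                raise ValueError(f"negative dimension for modality {m!r}")
            k = self.n_informative.get(m, 0)
            if k > d:
                raise ValueError(
                    f"n_informative[{m!r}]={k} exceeds modality_dims[{m!r}]={d}"
                )
            if d == 0 and k > 0:
                raise ValueError(f"modality {m!r} has 0 features but informative > 0")
        if (self.n_case == 0 or self.n_control == 0) and any(
            self.n_informative.get(m, 0) > 0 for m in self.modality_dims
        ):
            raise ValueError("cannot plant group effects with an empty group")
        if self.n_female_per_group > min(self.n_case, self.n_control) and (
            self.n_case and self.n_control
        ):
            raise ValueError("n_female_per_group exceeds group size")


@dataclass
class Cohort:
    """A generated cohort: aligned metadata and per-modality tables."""

    subject_ids: list[str]
    labels: np.ndarray  # +1 case / -1 control
    batches: np.ndarray  # integer batch ids
    covariates: pd.DataFrame  # age_months, sex, race (indexed like tables)
    features: dict[str, pd.DataFrame]  # modality -> subjects x features
    informative: dict[str, np.ndarray]  # ground truth column indices

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def meta_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "label": self.labels,
                "batch": self.batches,
            }
        )
        return pd.concat([meta, self.covariates.reset_index(drop=True)], axis=1)


def _block_correlated_noise(
    rng: np.random.Generator, n: int, d: int, rho: float, block: int
) -> np.ndarray:
    """N(0,1) marginals, exchangeable correlation ``rho`` within blocks."""
    eps = rng.standard_normal((n, d))
    if rho <= 0.0 or d == 0:
        return eps
    n_blocks = (d + block - 1) // block
    shared = rng.standard_normal((n, n_blocks))
    out = np.empty_like(eps)
    for b in range(n_blocks):
        cols = slice(b * block, min((b + 1) * block, d))
        out[:, cols] = np.sqrt(rho) * shared[:, [b]] + np.sqrt(1.0 - rho) * eps[:, cols]
    return out


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a cohort from the generative model; same seed, same cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    labels = np.concatenate(
        [np.ones(config.n_case, dtype=int), -np.ones(config.n_control, dtype=int)]
    )
    subject_ids = [f"S{i:04d}" for i in range(n)]

    # sex and race matched exactly between the groups
    def group_demo(size: int) -> tuple[np.ndarray, np.ndarray]:
        sex = np.array(
            ["F"] * min(config.n_female_per_group, size)
            + ["M"] * max(size - config.n_female_per_group, 0)
        )
        race_pool: list[str] = []
        total_r = sum(RACE_COUNTS.values())
        for r, c in RACE_COUNTS.items():
            race_pool += [r] * max(1, round(c * size / total_r)) if size else []
        race = np.array((race_pool * ((size // max(len(race_pool), 1)) + 1))[:size])
        return sex, race

    sex_case, race_case = group_demo(config.n_case)
    sex_ctrl, race_ctrl = group_demo(config.n_control)
    sex = np.concatenate([sex_case, sex_ctrl])
    race = np.concatenate([race_case, race_ctrl])

    age = np.concatenate(
        [
            rng.normal(config.age_mean_case, config.age_sd, config.n_case),
            rng.normal(config.age_mean_control, config.age_sd, config.n_control),
        ]
    )
    z_age = (age - age.mean()) / age.std() if n > 1 and age.std() > 0 else np.zeros(n)

    if config.confound_batch_with_label:
        # cases skewed toward later batches (off by default: groups matched)
        p = np.ones(config.n_batches)
        batches = np.empty(n, dtype=int)
        for i, y in enumerate(labels):
            w = p * (np.arange(config.n_batches) + 1.0) if y > 0 else p
            batches[i] = rng.choice(config.n_batches, p=w / w.sum())
    else:
        batches = rng.integers(0, config.n_batches, size=n)
    # guarantee every batch is populated (ComBat needs >=2 per batch)
    if n >= 2 * config.n_batches:
        order = rng.permutation(n)
        for b in range(config.n_batches):
            need = 2 - int(np.sum(batches == b))
            for _ in range(max(need, 0)):
                for idx in order:
                    if np.sum(batches == batches[idx]) > 2:
                        batches[idx] = b
                        break

    features: dict[str, pd.DataFrame] = {}
    informative: dict[str, np.ndarray] = {}
    for m in config.modality_dims:
        d = config.modality_dims[m]
        k = config.n_informative.get(m, 0)
        eps = _block_correlated_noise(
            rng, n, d, config.block_corr, config.block_size
        )
        # informative columns spread across blocks, not clustered in one
        info_idx = (
            np.unique(np.linspace(0, d - 1, k).round().astype(int))
            if k
            else np.array([], dtype=int)
        )
        u = rng.standard_normal((config.n_batches, d))  # additive batch draws
        v = rng.uniform(-1.0, 1.0, (config.n_batches, d))  # multiplicative draws
        scale = config.batch_scale ** v[batches]
        shift = config.batch_shift * u[batches]
        X = scale * eps + shift
        X += config.age_slope * z_age[:, None]
        if k:
            X[:, info_idx] += config.effect_size * (labels == 1)[:, None]
        cols = [f"{m}_f{j:04d}" for j in range(d)]
        features[m] = pd.DataFrame(X, columns=cols)
        informative[m] = info_idx

    covariates = pd.DataFrame({"age_months": age, "sex": sex, "race": race})
    return Cohort(subject_ids, labels, batches, covariates, features, informative)


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    """One CSV per modality plus meta.csv and truth.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = cohort.meta_frame()
    meta.to_csv(directory / "meta.csv", index=False, float_format="%.17g")
    for m, table in cohort.features.items():
        out = table.copy()
        out.insert(0, "subject_id", cohort.subject_ids)
        # %.17g guarantees binary round-trip of float64 values
        out.to_csv(directory / f"{m}.csv", index=False, float_format="%.17g")
    truth = {m: idx.tolist() for m, idx in cohort.informative.items()}
    (directory / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(directory: str | Path) -> Cohort:
    """Inverse of :func:`write_cohort`; validates alignment and columns."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "meta.csv")
    for col in ("subject_id", "label", "batch"):
        if col not in meta.columns:
            raise ValueError(f"meta.csv is missing required column {col!r}")
    subject_ids = meta["subject_id"].astype(str).tolist()
    features: dict[str, pd.DataFrame] = {}
    for path in sorted(directory.glob("*.csv")):
        if path.name == "meta.csv":
            continue
        table = pd.read_csv(path, float_precision="round_trip")
        if "subject_id" not in table.columns:
            raise ValueError(f"{path.name} is missing the subject_id column")
        ids = table["subject_id"].astype(str).tolist()
        if ids != subject_ids:
            raise ValueError(f"subject ids in {path.name} do not match meta.csv")
        features[path.stem] = table.drop(columns="subject_id")
    truth_path = directory / "truth.json"
    informative = (
        {m: np.asarray(v, dtype=int) for m, v in json.loads(truth_path.read_text()).items()}
        if truth_path.exists()
        else {m: np.array([], dtype=int) for m in features}
    )
    covars = meta[[c for c in meta.columns if c not in ("subject_id", "label", "batch")]]
    return Cohort(
        subject_ids=subject_ids,
        labels=meta["label"].to_numpy(),
        batches=meta["batch"].to_numpy(),
        covariates=covars,
        features=features,
        informative=informative,
    )
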