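"""Survey-shaped synthetic data generator.

Emulates a national cross-sectional survey of depressive symptoms: eight
age bins (12-19 ... 80-89), 20 CES-D items per respondent of which the 16
negative items follow the exponential category model with age-bin-dependent
(P, r), 4 positive-affect items drawn from a free-form category
distribution (they do not follow the model), plus a small fraction of
invalid responders who answer a single category ("rarely" or "most") for
every item.

Items are sampled independently given the age bin: the analysis models
only marginal per-item distributions, so no dependence structure is
imposed.  The default scenario's parameter trajectories are illustrative
choices that reproduce the qualitative age patterns of interest (U-shaped
r, comparatively flat P with a dip at 70-79), not estimates from any real
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core_model import ModelParams, category_probabilities
from .estimation import CategoryCounts
from .scoring import NEGATIVE_ITEMS, POSITIVE_AFFECT, item_columns

__all__ = [
    "AgeBin",
    "Scenario",
    "DEFAULT_AGE_BINS",
    "default_scenario",
    "constant_scenario",
    "sample_item",
    "generate_survey",
]

#: The eight age bins of the reference analysis, inclusive on both ends.
DEFAULT_AGE_BINS = (
    (12, 19),
    (20, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
    (80, 89),
)

# Default per-bin mean parameters.  r traces a U across age (high in youth
# and old age, low in middle adulthood); P is comparatively flat with a
# mild decline through 50-79 (lowest at 70-79) and an uptick at 80-89.
_DEFAULT_MEAN_P = (0.20, 0.21, 0.21, 0.21, 0.20, 0.18, 0.16, 0.19)
_DEFAULT_MEAN_R = (0.45, 0.42, 0.34, 0.33, 0.33, 0.38, 0.52, 0.55)

# Scored-value distribution (0..3) shared by the 4 positive-affect items;
# plateau-shaped across age, so it is constant per bin by default.
_DEFAULT_POSITIVE_DIST = (0.35, 0.35, 0.20, 0.10)


def bin_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


@dataclass(frozen=True)
class AgeBin:
    lo: int
    hi: int

    @property
    def label(self) -> str:
        return bin_label(self.lo, self.hi)


@dataclass(frozen=True)
class Scenario:
    """Full specification of one synthetic survey.

    ``params`` maps bin label -> {item id -> ModelParams} for the 16
    negative items; ``positive_dist`` maps bin label -> length-4 tuple of
    scored-value probabilities shared by the 4 positive items (stored in
    raw coding by the generator, i.e. reverse of the scored value).
    """

    age_bins: tuple[tuple[int, int], ...]
    n_per_bin: int
    params: dict[str, dict[int, ModelParams]]
    positive_dist: dict[str, tuple[float, float, float, float]]
    invalid_fraction: float = 0.02
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 <= self.invalid_fraction < 1.0):
            raise ValueError("invalid_fraction must be in [0, 1)")
        for label, dist in self.positive_dist.items():
            if abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                raise ValueError(f"positive_dist[{label}] is not a distribution")
        for lo, hi in self.age_bins:
            if hi < lo:
                raise ValueError(f"malformed age bin {lo}-{hi}")

    @property
    def bin_labels(self) -> list[str]:
        return [bin_label(lo, hi) for lo, hi in self.age_bins]

    def mean_params(self) -> pd.DataFrame:
        """Per-bin mean (P, r) over the 16 negative items."""
        rows = []
        for label in self.bin_labels:
            ps = [m.P for m in self.params[label].values()]
            rs = [m.r for m in self.params[label].values()]
            rows.append({"age_group": label, "mean_P": np.mean(ps), "mean_r": np.mean(rs)})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "age_bins": [list(b) for b in self.age_bins],
            "n_per_bin": self.n_per_bin,
            "invalid_fraction": self.invalid_fraction,
            "seed": self.seed,
            "params": {
                label: {str(i): [float(m.P), float(m.r)] for i, m in items.items()}
                for label, items in self.params.items()
            },
            "positive_dist": {k: list(v) for k, v in self.positive_dist.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(
            age_bins=tuple(tuple(b) for b in d["age_bins"]),
            n_per_bin=int(d["n_per_bin"]),
            params={
                label: {int(i): ModelParams(*pr) for i, pr in items.items()}
                for label, items in d["params"].items()
            },
            positive_dist={k: tuple(v) for k, v in d["positive_dist"].items()},
            invalid_fraction=float(d.get("invalid_fraction", 0.0)),
            seed=int(d.get("seed", 0)),
            name=d.get("name", "custom"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _jitter(n_items: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-zero item-level jitter so bin means equal the stated values."""
    j = rng.uniform(-scale, scale, size=n_items)
    return j - j.mean()


def default_scenario(n_per_bin: int = 2500, seed: int = 0) -> Scenario:
    """The reference scenario: U-shaped r, mild P dip at 70-79.

    Deterministic: the per-item jitter uses a fixed internal seed, so two
    calls with the same arguments return identical scenarios.  ``seed``
    only sets the sampling seed carried by the scenario.
    """
    jitter_rng = np.random.default_rng(20990)
    neg_items = sorted(NEGATIVE_ITEMS)
    # jitter P only: items within an age bin share the ratio r (that shared
    # ratio is what makes their log-scale frequency lines parallel)
    p_jit = _jitter(len(neg_items), 0.010, jitter_rng)
    params: dict[str, dict[int, ModelParams]] = {}
    positive: dict[str, tuple[float, float, float, float]] = {}
    for (lo, hi), mp, mr in zip(DEFAULT_AGE_BINS, _DEFAULT_MEAN_P, _DEFAULT_MEAN_R):
        label = bin_label(lo, hi)
        params[label] = {
            item: ModelParams(mp + p_jit[k], mr) for k, item in enumerate(neg_items)
        }
        positive[label] = _DEFAULT_POSITIVE_DIST
    return Scenario(
        age_bins=DEFAULT_AGE_BINS,
        n_per_bin=n_per_bin,
        params=params,
        positive_dist=positive,
        invalid_fraction=0.02,
        seed=seed,
        name="default-u-shaped",
    )


def constant_scenario(
    P: float = 0.20, r: float = 0.38, n_per_bin: int = 2500, seed: int = 0
) -> Scenario:
    """Null scenario: identical (P, r) in every bin and item (flat trajectories)."""
    params = {
        bin_label(lo, hi): {item: ModelParams(P, r) for item in sorted(NEGATIVE_ITEMS)}
        for lo, hi in DEFAULT_AGE_BINS
    }
    positive = {bin_label(lo, hi): _DEFAULT_POSITIVE_DIST for lo, hi in DEFAULT_AGE_BINS}
    return Scenario(
        age_bins=DEFAULT_AGE_BINS,
        n_per_bin=n_per_bin,
        params=params,
        positive_dist=positive,
        invalid_fraction=0.0,
        seed=seed,
        name="constant-null",
    )


def sample_item(params: ModelParams, n: int, seed: int | np.random.Generator) -> CategoryCounts:
    """Draw n multinomial responses from the model's category distribution."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.asarray(category_probabilities(params).as_tuple())
    counts = rng.multinomial(n, probs / probs.sum())
    return CategoryCounts(*(int(c) for c in counts))


def generate_survey(scenario: Scenario) -> pd.DataFrame:
    """Generate the respondent-level response matrix for a scenario.

    Returns a DataFrame with columns respondent_id, age, sex,
    item_1 ... item_20, all responses in raw 0-3 coding (positive items
    stored as answered: raw = 3 - scored value).  A round(invalid_fraction
    x total) subset of rows is overwritten with all-0 or all-3 responses.
    Byte-identical output for identical scenario + seed.
    """
    rng = np.random.default_rng(scenario.seed)
    frames = []
    rid = 0
    for (lo, hi) in scenario.age_bins:
        label = bin_label(lo, hi)
        n = scenario.n_per_bin
        ages = rng.integers(lo, hi + 1, size=n)
        sexes = np.where(rng.random(n) < 0.5, "F", "M")
        data = {"respondent_id": np.arange(rid, rid + n), "age": ages, "sex": sexes}
        rid += n
        bin_params = scenario.params[label]
        pos_dist = np.asarray(scenario.positive_dist[label])
        for i in range(1, 21):
            if i in NEGATIVE_ITEMS:
                probs = np.asarray(category_probabilities(bin_params[i]).as_tuple())
                data[f"item_{i}"] = rng.choice(4, size=n, p=probs / probs.sum())
            else:
                assert i in POSITIVE_AFFECT
                scored = rng.choice(4, size=n, p=pos_dist / pos_dist.sum())
                data[f"item_{i}"] = 3 - scored  # store raw coding
        frames.append(pd.DataFrame(data))
    df = pd.concat(frames, ignore_index=True)

    n_invalid = int(round(scenario.invalid_fraction * len(df)))
    if n_invalid > 0:
        idx = rng.choice(len(df), size=n_invalid, replace=False)
        fill = rng.choice([0, 3], size=n_invalid)
        cols = item_columns()
        for j, v in zip(idx, fill):
            df.loc[j, cols] = v
    for c in item_columns():
        df[c] = df[c].astype(np.int64)
    return df
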