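"""Synthetic survey sessions with known attentive / C-IER ground truth.

The generator emulates the structure of a computer-administered background
questionnaire: grouped respondents (country-by-language analogue), one screen
per scale, lognormal screen-time components (one or two attentive components
plus one C/IER component with a lower mean log time), attentive item
responses drawn from a generalized partial credit model at group-specific
trait levels, C/IER responses drawn from a style mix (uniform random,
straight-lining, full omission), omissions at rates conditional on the
latent state, and mildly dispersed sampling weights.

Default magnitudes follow the questionnaire setting the package targets:
about 2.1 s attentive geometric mean time per item versus about 1.1 s for
the C/IER component, a 6% C/IER share, four-item four-option Likert scales
starting at screen position 21.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .gpcm import MISSING, GpcmItemParams, GroupDistribution, gpcm_category_probs

STYLES = ("uniform", "straightline", "omit")


def minimum_sample_size(separation_d: float) -> float:
    """Rule-of-thumb minimal n for a trustworthy univariate Gaussian mixture
    decomposition, 8 / d^4, where d is the smallest standardized mean
    difference between any two components."""
    if not np.isfinite(separation_d) or separation_d <= 0:
        raise InvalidInputError("separation d must be positive")
    return 8.0 / separation_d ** 4


@dataclasses.dataclass
class SimulationConfig:
    """Ground-truth configuration for one synthetic questionnaire.

    ``cier_proportion`` may be a scalar or a (n_groups, n_scales) array.
    Log-time parameters refer to the log geometric mean time per item,
    ln(t)/J.  ``attentive_log_means`` may hold one or two components; the
    C/IER mean must be below the smallest attentive mean.
    """

    n_groups: int = 2
    n_per_group: int = 1000
    n_scales: int = 8
    n_items: int = 4
    n_categories: int = 3            # K; categories 0..K (K+1 options)
    cier_proportion: float | np.ndarray = 0.06
    attentive_log_means: tuple = (0.76,)   # ~2.1 s per item
    attentive_log_sds: tuple = (0.15,)
    attentive_mixing: tuple = (1.0,)
    cier_log_mean: float = 0.12            # ~1.1 s per item
    cier_log_sd: float = 0.15
    style_probs: tuple = (0.5, 0.3, 0.2)   # uniform / straightline / omit
    omission_rate_attentive: float = 0.02
    omission_rate_cier: float = 0.25       # per item, non-omit C/IER styles
    group_means: tuple | None = None       # default linspace(0, 0.5, G)
    group_sds: tuple | None = None         # default linspace(1.0, 1.2, G)
    item_params: list | None = None        # per scale list of GpcmItemParams
    first_position: int = 21
    last_position: int = 80
    sampling_weight_sd: float = 0.25       # lognormal sigma, mean-1 normalised
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.n_per_group < 1 or self.n_scales < 1:
            raise InvalidInputError("counts must be positive: n_groups / "
                                    "n_per_group / n_scales")
        if self.n_items < 1 or self.n_categories < 1:
            raise InvalidInputError("n_items and n_categories must be >= 1")
        p = np.asarray(self.cier_proportion, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise InvalidInputError("cier_proportion must lie in [0, 1]")
        if len(self.attentive_log_means) != len(self.attentive_log_sds) or \
                len(self.attentive_log_means) != len(self.attentive_mixing):
            raise InvalidInputError("attentive component tuples must align")
        if not np.isclose(sum(self.attentive_mixing), 1.0):
            raise InvalidInputError("attentive_mixing must sum to 1")
        if self.cier_log_mean >= min(self.attentive_log_means):
            raise InvalidInputError("cier_log_mean must be below every "
                                    "attentive component mean")
        if not np.isclose(sum(self.style_probs), 1.0) or \
                any(s < 0 for s in self.style_probs):
            raise InvalidInputError("style_probs must be a 3-simplex "
                                    "(uniform, straightline, omit)")
        for name in ("omission_rate_attentive", "omission_rate_cier"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidInputError(f"{name} must lie in [0, 1]")

    @property
    def separation(self) -> float:
        """Standardized mean difference between the C/IER component and the
        closest attentive component."""
        gap = min(self.attentive_log_means) - self.cier_log_mean
        return gap / max(max(self.attentive_log_sds), self.cier_log_sd)

    @classmethod
    def with_separation(cls, d: float, **kwargs):
        """Config whose C/IER / attentive log-time separation equals d."""
        cfg = cls(**kwargs)
        sd = max(max(cfg.attentive_log_sds), cfg.cier_log_sd)
        object.__setattr__(cfg, "cier_log_mean",
                           min(cfg.attentive_log_means) - d * sd)
        return cfg


@dataclasses.dataclass
class SimulatedDataset:
    screen_records: pd.DataFrame
    responses: dict                 # scale_id -> wide DataFrame
    truth: pd.DataFrame             # respondent x scale latent labels
    scale_covariates: pd.DataFrame
    item_params: list               # per scale, list of GpcmItemParams
    group_distributions: list
    config: SimulationConfig


def _default_item_params(cfg: SimulationConfig, rng) -> list:
    out = []
    for _ in range(cfg.n_scales):
        items = []
        for _ in range(cfg.n_items):
            a = float(np.exp(rng.normal(0.0, 0.2)))
            loc = rng.normal(0.0, 0.5)
            steps = np.sort(rng.normal(loc, 0.7, cfg.n_categories))
            items.append(GpcmItemParams(a, steps))
        out.append(items)
    return out


def _draw_gpcm_responses(items, theta, rng):
    """(n, J) attentive responses from the GPCM at trait values theta."""
    n = theta.size
    out = np.empty((n, len(items)), dtype=int)
    for j, it in enumerate(items):
        p = gpcm_category_probs(it, theta)        # (n, K+1)
        u = rng.uniform(size=n)
        out[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return out


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Draw one complete synthetic dataset; deterministic given config.seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    G, S, J, K = cfg.n_groups, cfg.n_scales, cfg.n_items, cfg.n_categories
    n = cfg.n_per_group

    gmeans = (np.linspace(0.0, 0.5, G) if cfg.group_means is None
              else np.asarray(cfg.group_means, float))
    gsds = (np.linspace(1.0, 1.2, G) if cfg.group_sds is None
            else np.asarray(cfg.group_sds, float))
    if gmeans.shape != (G,) or gsds.shape != (G,):
        raise InvalidInputError("group_means / group_sds must have length "
                                "n_groups")
    item_params = (cfg.item_params if cfg.item_params is not None
                   else _default_item_params(cfg, rng))
    if len(item_params) != S:
        raise InvalidInputError("item_params must list one item set per scale")

    pis = np.broadcast_to(np.asarray(cfg.cier_proportion, float),
                          (G, S)).copy()
    positions = np.unique(np.round(
        np.linspace(cfg.first_position, cfg.last_position, S)).astype(int))
    while positions.size < S:  # guard against rounding collisions
        positions = np.append(positions, positions[-1] + 1)
    scale_ids = [f"S{p:03d}" for p in positions]

    cov_rows = []
    for s in range(S):
        cov_rows.append({
            "scale_id": scale_ids[s], "screen_position": int(positions[s]),
            "n_items": J, "n_options": K + 1,
            "avg_length": float(np.round(rng.uniform(2.0, 18.0), 2)),
        })
    scale_covariates = pd.DataFrame(cov_rows)

    rec_rows, truth_rows = [], []
    responses = {sid: [] for sid in scale_ids}

    for g in range(G):
        gid = f"G{g + 1:02d}"
        rid = np.array([f"{gid}_R{i + 1:05d}" for i in range(n)])
        theta = rng.normal(gmeans[g], gsds[g], size=n)
        v = rng.lognormal(0.0, cfg.sampling_weight_sd, size=n)
        v = v / v.mean()
        for s in range(S):
            sid = scale_ids[s]
            is_cier = rng.uniform(size=n) < pis[g, s]
            x = np.where(
                is_cier,
                rng.normal(cfg.cier_log_mean, cfg.cier_log_sd, size=n),
                _attentive_log_times(cfg, rng, n))
            times = np.exp(J * x)  # x is the per-item log time ln(t)/J

            resp = _draw_gpcm_responses(item_params[s], theta, rng)
            om_att = rng.uniform(size=(n, J)) < cfg.omission_rate_attentive
            resp[om_att] = MISSING

            style = np.full(n, "", dtype=object)
            idx = np.nonzero(is_cier)[0]
            if idx.size:
                style_idx = rng.choice(3, size=idx.size, p=cfg.style_probs)
                style[idx] = np.asarray(STYLES)[style_idx]
                for i, st in zip(idx, style_idx):
                    if st == 0:      # uniform random over categories
                        resp[i] = rng.integers(0, K + 1, size=J)
                    elif st == 1:    # straight line on one random category
                        resp[i] = rng.integers(0, K + 1)
                    else:            # full omission
                        resp[i] = MISSING
                    if st != 2:
                        om = rng.uniform(size=J) < cfg.omission_rate_cier
                        resp[i, om] = MISSING

            rec_rows.append(pd.DataFrame({
                "respondent_id": rid, "group_id": gid, "scale_id": sid,
                "time_seconds": times, "n_items": J, "sampling_weight": v,
            }))
            truth_rows.append(pd.DataFrame({
                "respondent_id": rid, "group_id": gid, "scale_id": sid,
                "is_cier": is_cier.astype(int), "style": style,
                "theta": theta,
            }))
            wide = pd.DataFrame(
                np.where(resp == MISSING, np.nan, resp),
                columns=[f"item_{j + 1}" for j in range(J)])
            wide.insert(0, "respondent_id", rid)
            wide.insert(1, "group_id", gid)
            responses[sid].append(wide)

    responses = {sid: pd.concat(parts, ignore_index=True)
                 for sid, parts in responses.items()}
    return SimulatedDataset(
        screen_records=pd.concat(rec_rows, ignore_index=True),
        responses=responses,
        truth=pd.concat(truth_rows, ignore_index=True),
        scale_covariates=scale_covariates,
        item_params=item_params,
        group_distributions=[GroupDistribution(float(m), float(s))
                             for m, s in zip(gmeans, gsds)],
        config=cfg)


def _attentive_log_times(cfg: SimulationConfig, rng, n):
    comp = rng.choice(len(cfg.attentive_mixing), size=n,
                      p=np.asarray(cfg.attentive_mixing))
    mu = np.asarray(cfg.attentive_log_means)[comp]
    sd = np.asarray(cfg.attentive_log_sds)[comp]
    return rng.normal(mu, sd)
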