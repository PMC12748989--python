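"""Hotspot registry and posterior-sampling goal selection.

Each candidate hotspot — a location on the board where a high-activity
peptide was discovered — is treated as an arm of a multi-armed bandit.  The
episode returns observed when the agent reaches hotspot *i* are modeled as
Gaussian with unknown mean and variance under a conjugate
Normal-Inverse-Gamma prior, so posterior draws are exact Gibbs draws
(variance from an inverse-gamma, mean from a normal given that variance).

During *training* the goal h_target is chosen by Thompson sampling: draw one
posterior mean per hotspot, take the argmax, and keep updating posteriors as
returns come in.  During *inference* the posterior summaries (mu_i, sigma_i)
are frozen; goals are drawn as h_target = argmax_i X_i with
X_i ~ N(mu_i, sigma_i) and no posterior update ever occurs.  sigma_i is the
posterior scale of the *mean* (sqrt(beta_n / (alpha_n kappa_n))), not the
predictive scale of a new observation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class PriorConfig:
    """Normal-Inverse-Gamma prior: mean mu0 with pseudo-count kappa0,
    variance with shape alpha0 / scale beta0 (prior E[var] = beta0/(alpha0-1),
    defaults give prior sigma ~ 1 on normalized rewards)."""

    mu0: float = 0.0
    kappa0: float = 1.0
    alpha0: float = 2.0
    beta0: float = 1.0


@dataclass
class Hotspot:
    """A candidate goal with its reward observations and posterior summary."""

    id: int
    location: np.ndarray
    best_prediction: float
    observations: list[float] = field(default_factory=list)
    mu_i: float = 0.0
    sigma_i: float = 1.0

    def posterior_params(self, prior: PriorConfig) -> tuple[float, float, float, float]:
        """Closed-form conjugate update -> (mu_n, kappa_n, alpha_n, beta_n)."""
        obs = np.asarray(self.observations, dtype=float)
        n = len(obs)
        kappa_n = prior.kappa0 + n
        alpha_n = prior.alpha0 + n / 2.0
        if n == 0:
            return prior.mu0, kappa_n, alpha_n, prior.beta0
        xbar = float(obs.mean())
        ss = float(((obs - xbar) ** 2).sum())
        mu_n = (prior.kappa0 * prior.mu0 + n * xbar) / kappa_n
        beta_n = (
            prior.beta0
            + 0.5 * ss
            + 0.5 * prior.kappa0 * n * (xbar - prior.mu0) ** 2 / kappa_n
        )
        return mu_n, kappa_n, alpha_n, beta_n

    def refresh_summary(self, prior: PriorConfig) -> None:
        mu_n, kappa_n, alpha_n, beta_n = self.posterior_params(prior)
        self.mu_i = mu_n
        self.sigma_i = float(np.sqrt(beta_n / (alpha_n * kappa_n)))

    def sample_mean(self, prior: PriorConfig, rng: np.random.Generator) -> float:
        """Exact Gibbs draw of the mean: var ~ InvGamma(alpha_n, beta_n),
        mean ~ N(mu_n, var / kappa_n)."""
        mu_n, kappa_n, alpha_n, beta_n = self.posterior_params(prior)
        var = beta_n / rng.gamma(alpha_n)
        return float(rng.normal(mu_n, np.sqrt(var / kappa_n)))


class HotspotSet:
    """The candidate set H_c with the current target and prior parameters.

    Hotspots closer than ``merge_radius`` (the goal radius) merge rather than
    duplicate, keeping the higher best_prediction.
    """

    def __init__(self, prior: PriorConfig | None = None, merge_radius: float = 0.08) -> None:
        self.prior = prior or PriorConfig()
        self.merge_radius = merge_radius
        self.candidates: list[Hotspot] = []
        self.current_target: Hotspot | None = None
        self._next_id = 0

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def best_prediction(self) -> float:
        return max((h.best_prediction for h in self.candidates), default=-np.inf)

    def register(self, location: np.ndarray, prediction: float) -> Hotspot:
        """Add a candidate (or merge into one within the merge radius)."""
        if not 0.0 <= prediction <= 100.0:
            raise ValueError(f"prediction must be a percent in [0, 100], got {prediction}")
        location = np.asarray(location, dtype=float)
        for h in self.candidates:
            if float(np.hypot(*(h.location - location))) <= self.merge_radius:
                if prediction > h.best_prediction:
                    h.best_prediction = prediction
                    h.location = location
                return h
        hs = Hotspot(id=self._next_id, location=location, best_prediction=prediction)
        hs.refresh_summary(self.prior)
        self._next_id += 1
        self.candidates.append(hs)
        if self.current_target is None:
            self.current_target = hs
        return hs

    def update_posterior(self, hotspot: Hotspot, observation: float) -> Hotspot:
        if not np.isfinite(observation):
            raise ValueError("observation must be finite")
        hotspot.observations.append(float(observation))
        hotspot.refresh_summary(self.prior)
        return hotspot

    def select_target_training(self, rng: np.random.Generator) -> Hotspot:
        """Thompson selection: one posterior-mean draw per arm, argmax;
        ties broken by lowest id."""
        if not self.candidates:
            raise ValueError("no candidate hotspots registered")
        draws = np.array([h.sample_mean(self.prior, rng) for h in self.candidates])
        best = int(np.argmax(draws))  # argmax returns the first (lowest-id) max
        self.current_target = self.candidates[best]
        return self.current_target

    def select_target_inference(self, rng: np.random.Generator) -> Hotspot:
        """Frozen-parameter selection: X_i ~ N(mu_i, sigma_i), argmax.
        Never mutates any posterior."""
        if not self.candidates:
            raise ValueError("no candidate hotspots registered")
        draws = np.array(
            [rng.normal(h.mu_i, h.sigma_i) for h in self.candidates]
        )
        best = int(np.argmax(draws))
        self.current_target = self.candidates[best]
        return self.current_target

    # -- serialization (the trained policy's companion state) --------------

    def to_dict(self) -> dict:
        return {
            "prior": vars(self.prior),
            "merge_radius": self.merge_radius,
            "next_id": self._next_id,
            "current_target": None if self.current_target is None else self.current_target.id,
            "candidates": [
                {
                    "id": h.id,
                    "location": h.location.tolist(),
                    "best_prediction": h.best_prediction,
                    "observations": h.observations,
                    "mu_i": h.mu_i,
                    "sigma_i": h.sigma_i,
                }
                for h in self.candidates
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "HotspotSet":
        hs = cls(prior=PriorConfig(**d["prior"]), merge_radius=d["merge_radius"])
        hs._next_id = d["next_id"]
        for c in d["candidates"]:
            h = Hotspot(
                id=c["id"],
                location=np.array(c["location"]),
                best_prediction=c["best_prediction"],
                observations=list(c["observations"]),
                mu_i=c["mu_i"],
                sigma_i=c["sigma_i"],
            )
            hs.candidates.append(h)
            if d["current_target"] == h.id:
                hs.current_target = h
        return hs

    @classmethod
    def from_json(cls, path: str | Path) -> "HotspotSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def state_hash(self) -> str:
        """Hash of the frozen posterior state (candidates, observations,
        prior).  The ephemeral current-target pointer is excluded: goal
        selection is not a posterior mutation."""
        d = self.to_dict()
        d.pop("current_target")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
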