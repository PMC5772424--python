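"""Demographic models of Bornean-elephant colonization history and their priors.

Seven backward-time demographic scenarios are supported, identified by short
codes:

``ID``
    instantaneous decline: constant current size ``N_cur`` until ``T_shrink``
    generations ago, ancestral size ``N_anc`` before that.
``ED``
    exponential decline from ``N_anc`` (at ``T_shrink``) to ``N_cur`` (now).
``AC``
    ancient colonization: a founder group of ``N_shrink`` individuals split
    off a large ancestral population (``N_anc``) ``T_shrink`` generations ago
    and grew exponentially to ``N_cur``.
``RI``
    recent introduction from Sulu/Java: same shape as ``AC`` but with a
    recent founder event and a much smaller source population.
``TI``
    two introductions: an older founder event at ``T_first`` (Java -> Sulu)
    followed by a second founder event at ``T_shrink`` (Sulu -> Borneo).
``ACS`` / ``RIS``
    as ``AC`` / ``RI`` with the present-day population fragmented into four
    demes (no migration) from ``T_split`` generations ago to the present.

All sizes are effective numbers of diploid individuals, all times are
generations before sampling (t=0 is the present), and gradual size changes
are exponential in time.  A drawn parameter vector is turned into a
:class:`DemographyRealization` — a piecewise-exponential size history that
the coalescent engine consumes directly.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import yaml

MODEL_IDS = ("ID", "ED", "AC", "RI", "TI", "ACS", "RIS")

#: parameters each model's demography builder consumes
MODEL_PARAM_NAMES = {
    "ID": ("N_anc", "N_cur", "T_shrink", "mu", "p_gsm"),
    "ED": ("N_anc", "N_cur", "T_shrink", "mu", "p_gsm"),
    "AC": ("N_anc", "N_cur", "T_shrink", "N_shrink", "mu", "p_gsm"),
    "RI": ("N_anc", "N_cur", "T_shrink", "N_shrink", "mu", "p_gsm"),
    "TI": ("N_anc", "N_intermediate", "N_cur", "T_shrink", "T_first",
           "N_shrink", "N_shrink_first", "mu", "p_gsm"),
    "ACS": ("N_anc", "N_cur", "T_shrink", "N_shrink", "T_split", "mu", "p_gsm"),
    "RIS": ("N_anc", "N_cur", "T_shrink", "N_shrink", "T_split", "mu", "p_gsm"),
}

STRUCTURED_MODELS = ("ACS", "RIS")
DEFAULT_N_DEMES = 4
DEFAULT_GENERATION_TIME_YEARS = 15.0


class ConfigurationError(ValueError):
    """A model/prior configuration is inconsistent or incomplete."""


@dataclass(frozen=True)
class PriorSpec:
    """A one-dimensional prior.

    ``uniform`` bounds are on the natural scale of the parameter;
    ``loguniform`` bounds are base-10 exponents (a draw is ``10**u`` with
    ``u ~ Uniform(low, high)``).  ``low == high`` gives a point prior.
    """

    kind: str  # "uniform" | "loguniform"
    low: float
    high: float

    def __post_init__(self):
        if self.kind not in ("uniform", "loguniform"):
            raise ConfigurationError(f"unknown prior kind {self.kind!r}")
        if self.low > self.high:
            raise ConfigurationError(
                f"inverted prior bounds [{self.low}, {self.high}]")

    def draw(self, rng: np.random.Generator) -> float:
        u = self.low if self.low == self.high else rng.uniform(self.low, self.high)
        return 10.0 ** u if self.kind == "loguniform" else u

    @property
    def support(self) -> tuple[float, float]:
        """Bounds on the natural (linear) parameter scale."""
        if self.kind == "loguniform":
            return (10.0 ** self.low, 10.0 ** self.high)
        return (self.low, self.high)


@dataclass(frozen=True)
class ModelSpec:
    """A demographic scenario plus priors for its parameters."""

    model_id: str
    priors: dict[str, PriorSpec]
    n_demes: int = 1
    deme_names: tuple[str, ...] = ()
    generation_time_years: float = DEFAULT_GENERATION_TIME_YEARS

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ConfigurationError(f"unknown model id {self.model_id!r}")
        if self.generation_time_years <= 0:
            raise ConfigurationError("generation_time_years must be > 0")
        missing = [p for p in MODEL_PARAM_NAMES[self.model_id]
                   if p not in self.priors]
        if missing:
            raise ConfigurationError(
                f"model {self.model_id}: missing PriorSpec for "
                + ", ".join(missing))

    @property
    def param_names(self) -> tuple[str, ...]:
        return MODEL_PARAM_NAMES[self.model_id]


@dataclass(frozen=True)
class ModelParams:
    """One drawn parameter vector.  Fields unused by a model are ``None``."""

    N_anc: float
    N_cur: float
    mu: float
    p_gsm: float
    T_shrink: float
    N_shrink: float | None = None
    T_first: float | None = None
    N_shrink_first: float | None = None
    N_intermediate: float | None = None
    T_split: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


_MAX_RESAMPLE = 1_000_000


def draw_params(spec: ModelSpec, rng: np.random.Generator) -> ModelParams:
    """Draw one parameter vector from a model's priors.

    Structural constraints (``T_first > T_shrink`` for TI; ``0 < T_split <=
    T_shrink`` for ACS/RIS) are enforced by rejection-resampling the
    constrained parameter only, so the remaining marginals stay untouched
    and the conditional of the constrained one is uniform on its admissible
    range.
    """
    values = {name: spec.priors[name].draw(rng) for name in spec.param_names}
    if spec.model_id == "TI":
        for _ in range(_MAX_RESAMPLE):
            if values["T_first"] > values["T_shrink"]:
                break
            values["T_first"] = spec.priors["T_first"].draw(rng)
        else:
            raise ConfigurationError(
                "TI: could not satisfy T_first > T_shrink; check the "
                "T_first/T_shrink priors")
    if spec.model_id in STRUCTURED_MODELS:
        for _ in range(_MAX_RESAMPLE):
            if 0.0 < values["T_split"] <= values["T_shrink"]:
                break
            values["T_split"] = spec.priors["T_split"].draw(rng)
        else:
            raise ConfigurationError(
                f"{spec.model_id}: could not satisfy 0 < T_split <= T_shrink")
    return ModelParams(**values)


@dataclass(frozen=True)
class Epoch:
    """One piecewise-exponential epoch, backward in time.

    On ``[t_start, t_end)`` the *total* population size is
    ``N(t) = n_total * exp(-alpha * (t - t_start))`` (``alpha`` is the
    forward-time growth rate, so sizes shrink going backward when
    ``alpha > 0``), split equally over ``n_demes`` demes.
    """

    t_start: float
    n_total: float
    alpha: float
    n_demes: int


@dataclass(frozen=True)
class DemographyRealization:
    """A fully specified size-through-time history for one parameter draw."""

    model_id: str
    epochs: tuple[Epoch, ...]
    deme_names: tuple[str, ...]

    def __post_init__(self):
        ts = [e.t_start for e in self.epochs]
        if ts != sorted(ts) or len(set(ts)) != len(ts):
            raise ValueError("epochs must be strictly increasing in t_start")
        if self.epochs[0].t_start != 0.0:
            raise ValueError("first epoch must start at t=0")
        last = self.epochs[-1]
        if last.alpha != 0.0 or last.n_demes != 1:
            raise ValueError("oldest epoch must be a single constant-size deme")
        for e in self.epochs:
            if min(self.deme_sizes_at(max(e.t_start, 0.0))) < 1.0:
                raise ValueError(f"deme size < 1 at t={e.t_start}")

    def _epoch_at(self, t: float) -> Epoch:
        ep = self.epochs[0]
        for e in self.epochs:
            if e.t_start <= t:
                ep = e
        return ep

    def size_at(self, t: float) -> float:
        """Total effective size (diploid individuals) at time ``t`` back."""
        e = self._epoch_at(t)
        return e.n_total * math.exp(-e.alpha * (t - e.t_start))

    def n_demes_at(self, t: float) -> int:
        return self._epoch_at(t).n_demes

    def deme_sizes_at(self, t: float) -> np.ndarray:
        e = self._epoch_at(t)
        return np.full(e.n_demes, self.size_at(t) / e.n_demes)

    @property
    def events(self) -> list[tuple[float, str]]:
        """Backward-time event list (epoch boundaries, oldest last)."""
        out = []
        for prev, e in zip(self.epochs, self.epochs[1:]):
            kind = []
            if e.n_demes != prev.n_demes:
                kind.append(f"demes {prev.n_demes}->{e.n_demes}")
            kind.append("size change")
            out.append((e.t_start, ", ".join(kind)))
        return out

    def kernel_epochs(self, pair_size_factor: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays for the coalescent kernel.

        ``pair_size_factor`` converts a diploid census-style size N into the
        per-deme "coalescent size" C such that a pair of lineages in a deme
        coalesces at rate 1/C: 2 for autosomal-diploid copies, or the female
        fraction (e.g. 0.25) for mitochondrial lineages.
        """
        t0 = np.array([e.t_start for e in self.epochs])
        c0 = np.array([pair_size_factor * e.n_total / e.n_demes
                       for e in self.epochs])
        al = np.array([e.alpha for e in self.epochs])
        nd = np.array([e.n_demes for e in self.epochs], dtype=np.int64)
        return t0, c0, al, nd


def _growth_rate(n_recent: float, n_old: float, span: float) -> float:
    # forward-time exponential rate taking n_old (at the older end) to
    # n_recent over `span` generations
    return math.log(n_recent / n_old) / span


def build_demography(model_id: str, params: ModelParams,
                     n_demes: int = DEFAULT_N_DEMES,
                     deme_names: tuple[str, ...] = (),
                     ) -> DemographyRealization:
    """Turn a parameter draw into a piecewise demographic history."""
    p = params
    if model_id == "ID":
        eps = [Epoch(0.0, p.N_cur, 0.0, 1)]
        if p.N_anc != p.N_cur:  # degenerate decline: no effective event
            eps.append(Epoch(p.T_shrink, p.N_anc, 0.0, 1))
        else:
            eps = [Epoch(0.0, p.N_anc, 0.0, 1)]
    elif model_id == "ED":
        al = _growth_rate(p.N_cur, p.N_anc, p.T_shrink)
        eps = [Epoch(0.0, p.N_cur, al, 1),
               Epoch(p.T_shrink, p.N_anc, 0.0, 1)]
    elif model_id in ("AC", "RI"):
        al = _growth_rate(p.N_cur, p.N_shrink, p.T_shrink)
        eps = [Epoch(0.0, p.N_cur, al, 1),
               Epoch(p.T_shrink, p.N_anc, 0.0, 1)]
    elif model_id == "TI":
        al1 = _growth_rate(p.N_cur, p.N_shrink, p.T_shrink)
        al2 = _growth_rate(p.N_intermediate, p.N_shrink_first,
                           p.T_first - p.T_shrink)
        eps = [Epoch(0.0, p.N_cur, al1, 1),
               Epoch(p.T_shrink, p.N_intermediate, al2, 1),
               Epoch(p.T_first, p.N_anc, 0.0, 1)]
    elif model_id in STRUCTURED_MODELS:
        al = _growth_rate(p.N_cur, p.N_shrink, p.T_shrink)
        n_at_split = p.N_cur * math.exp(-al * p.T_split)
        eps = [Epoch(0.0, p.N_cur, al, n_demes)]
        if p.T_split < p.T_shrink:
            eps.append(Epoch(p.T_split, n_at_split, al, 1))
        eps.append(Epoch(p.T_shrink, p.N_anc, 0.0, 1))
    else:
        raise ConfigurationError(f"unknown model id {model_id!r}")
    if not deme_names:
        nd = n_demes if model_id in STRUCTURED_MODELS else 1
        deme_names = tuple(f"deme{i}" for i in range(nd))
    return DemographyRealization(model_id, tuple(eps), deme_names)


def load_model_specs(path=None) -> dict[str, ModelSpec]:
    """Read model/prior configuration (YAML); defaults ship with the package.

    The file maps model id -> {parameter -> {kind, min, max}}, with optional
    top-level ``generation_time_years``.
    """
    if path is None:
        ref = importlib.resources.files("borneoabc") / "config" / "models.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    gtime = float(doc.get("generation_time_years",
                          DEFAULT_GENERATION_TIME_YEARS))
    specs = {}
    for mid, block in doc["models"].items():
        priors = {}
        for pname, pr in block["priors"].items():
            try:
                priors[pname] = PriorSpec(pr["kind"], float(pr["min"]),
                                          float(pr["max"]))
            except ConfigurationError as err:
                raise ConfigurationError(f"{mid}.{pname}: {err}") from err
        n_demes = int(block.get("demes", 1))
        specs[mid] = ModelSpec(model_id=mid, priors=priors, n_demes=n_demes,
                               generation_time_years=gtime)
    return specs


def default_model_specs() -> dict[str, ModelSpec]:
    return load_model_specs(None)
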