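"""Synthetic cohorts for the semantic-foraging pipeline.

Generates the full data structure the analysis assumes, with ground truth
recorded for recovery tests:

* a semantic space of polysemous cues, each with several abstract meanings and
  unit-norm word embeddings clustered by meaning;
* fluency sessions produced by a marginal-value-theorem (MVT) forager whose
  deviations from the optimal policy (fast switches, slow clustering) occur at
  tunable rates;
* per-subject functional-connectivity matrices with edge-trait effects planted
  on known edges;
* covariate and creativity scores generated through a mediated
  brain -> search-pattern -> creativity structure.

The foraging agent retrieves words from the meaning cluster it currently
occupies.  Within-cluster inter-response times (IRTs) are lognormal with a mean
that grows geometrically with the position in the cluster (patch depletion).
The agent leaves the cluster when the prospective next IRT reaches a fixed
fraction (``threshold_frac``) of its running mean IRT -- the marginal value it
can estimate mid-trial.  Switch IRTs carry an additive travel cost.  Two
deviations from this policy are injected at per-decision Bernoulli rates:
*fast switches* (a switch emitted before the threshold, at within-cluster
speed, no travel cost) and *slow clustering* (persisting past the threshold,
paying a retrieval cost comparable to a switch while staying in the meaning).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "SemanticSpace",
    "ForagingPolicy",
    "SessionTruth",
    "GroundTruth",
    "CohortConfig",
    "Cohort",
    "generate_semantic_space",
    "generate_fluency_session",
    "generate_connectivity",
    "generate_mediation_triple",
    "generate_cohort",
    "DEFAULT_NETWORK_NAMES",
]

ARTICULATION_S = 0.4  # fixed response duration; offsets = onset + this

# Short names in the style of the 7-network cortical parcellations.
DEFAULT_NETWORK_NAMES = ("Vis", "Som", "DAN", "Sal", "Limbic", "ECN", "DMN")


# ---------------------------------------------------------------------------
# Semantic space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SemanticSpace:
    """Cue/meaning lexicon plus unit-norm embeddings.

    ``lexicon`` maps each word to its ``(cue, meaning_id)``; ``embeddings``
    maps each word to a unit-norm vector.  Every lexicon word has exactly one
    embedding of the common dimension.
    """

    cues: tuple[str, ...]
    meanings_per_cue: int
    lexicon: dict[str, tuple[str, int]]
    embeddings: dict[str, np.ndarray]

    @property
    def dim(self) -> int:
        first = next(iter(self.embeddings.values()))
        return int(first.shape[0])

    def words_for(self, cue: str) -> dict[int, list[str]]:
        """Words of one cue, grouped by meaning id (lexicon order)."""
        out: dict[int, list[str]] = {}
        for word, (c, m) in self.lexicon.items():
            if c == cue:
                out.setdefault(m, []).append(word)
        return out


def generate_semantic_space(
    n_cues: int,
    n_meanings: int,
    words_per_meaning: int,
    dim: int,
    within_sd: float,
    seed: int | np.random.Generator,
) -> SemanticSpace:
    """Draw meaning centroids uniformly on the unit sphere and cluster words
    around them.

    Words within a meaning are eccentricity-graded: the noise applied to word
    ``w`` scales from 0.5x to 1.5x ``within_sd`` across the pool, so
    low-index words are prototypical members and high-index words peripheral
    ones.  The foraging agent retrieves central words first, which couples
    retrieval depth (and hence IRT) to falling inter-response similarity --
    the longer it takes to retrieve a word, the less similar it tends to be
    to its predecessor.  With ``within_sd == 0`` all words of a meaning share
    the centroid vector exactly (within-meaning cosine 1).
    """
    if n_cues < 1 or n_meanings < 1 or words_per_meaning < 1:
        raise ValueError("counts must be >= 1")
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if within_sd < 0:
        raise ValueError("within_sd must be non-negative")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cues = tuple(f"cue{i:02d}" for i in range(n_cues))
    lexicon: dict[str, tuple[str, int]] = {}
    embeddings: dict[str, np.ndarray] = {}
    for cue in cues:
        for m in range(n_meanings):
            centroid = rng.standard_normal(dim)
            centroid /= np.linalg.norm(centroid)
            for w in range(words_per_meaning):
                word = f"{cue}_m{m}_w{w:02d}"
                vec = centroid.copy()
                if within_sd > 0:
                    ecc = 0.5 + w / max(1, words_per_meaning - 1)
                    vec = vec + rng.normal(0.0, within_sd * ecc, size=dim)
                    vec /= np.linalg.norm(vec)
                lexicon[word] = (cue, m)
                embeddings[word] = vec
    return SemanticSpace(cues, n_meanings, lexicon, embeddings)


# ---------------------------------------------------------------------------
# Foraging policy and session generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForagingPolicy:
    """Parameters of the MVT forager.

    mu_cluster
        Mean IRT (s) of the first within-cluster retrieval after a switch.
    switch_cost
        Additive IRT cost (s) of travelling to a new cluster; also paid by
        slow-clustering deviants that keep digging in a depleted cluster.
    ramp
        Multiplicative IRT growth per successive within-cluster item
        (patch depletion; >= 1).
    p_fast_switch
        Per-decision probability of switching before the marginal value is
        reached (over-exploration); these switches come at within-cluster
        speed and pay no travel cost.
    p_slow_cluster
        Per-decision probability of persisting after the marginal value is
        exceeded (over-exploitation).
    noise_sd
        Log-scale standard deviation of the lognormal IRT noise.
    trial_duration
        Time budget per cue (s).
    threshold_frac
        Fraction of the running-mean IRT at which the agent leaves the
        cluster.  Below 1 the agent switches slightly before its marginal
        value, matching the empirical pattern that mean pre-switch IRT ratios
        sit below 1.
    """

    mu_cluster: float = 2.0
    switch_cost: float = 3.0
    ramp: float = 1.3
    p_fast_switch: float = 0.15
    p_slow_cluster: float = 0.2
    noise_sd: float = 0.25
    trial_duration: float = 60.0
    threshold_frac: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_fast_switch <= 1.0 and 0.0 <= self.p_slow_cluster <= 1.0):
            raise ValueError("deviation probabilities must lie in [0, 1]")
        if self.mu_cluster <= 0:
            raise ValueError("mu_cluster must be positive")
        if self.trial_duration < 0:
            raise ValueError("trial_duration must be non-negative")
        if self.ramp < 1.0:
            raise ValueError("ramp must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 < self.threshold_frac <= 1.0):
            raise ValueError("threshold_frac must lie in (0, 1]")

    def scaled(self, factor: float) -> "ForagingPolicy":
        """Multiply the time scale (mu_cluster and switch_cost) by ``factor``."""
        return replace(self, mu_cluster=float(self.mu_cluster * factor),
                       switch_cost=float(self.switch_cost * factor))


@dataclass
class SessionTruth:
    """Generator-side record of one session, for recovery tests.

    ``kinds`` holds, per emitted response, the true generating event:
    ``initial``, ``C`` (within-cluster), ``S`` (threshold switch), ``FS``
    (fast-switch deviant), ``SC`` (slow-clustering deviant), ``S_forced`` /
    ``C_forced`` (lexicon exhaustion, not a free decision).
    ``n_free_decisions`` / ``n_threshold_decisions`` count decision
    opportunities that resulted in an emitted response: the binomial
    denominators for ``p_fast_switch`` and ``p_slow_cluster``.
    """

    participant: str
    cue: str
    kinds: list[str]
    n_free_decisions: int
    n_threshold_decisions: int

    @property
    def n_fast_switch(self) -> int:
        return sum(k == "FS" for k in self.kinds)

    @property
    def n_slow_cluster(self) -> int:
        return sum(k == "SC" for k in self.kinds)


def _lognormal_mean(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Lognormal draw parameterized by its arithmetic mean; degenerate at sd=0."""
    if sd == 0.0:
        return mean
    return float(np.exp(rng.normal(np.log(mean) - 0.5 * sd * sd, sd)))


def generate_fluency_session(
    space: SemanticSpace,
    policy: ForagingPolicy,
    cue: str,
    seed: int | np.random.Generator,
    participant: str = "p000",
) -> tuple[pd.DataFrame, SessionTruth]:
    """Simulate one fluency trial for one cue.

    Returns the response-log rows (participant, cue, response_index, word,
    onset, offset, meaning) and the session's ground truth.  Responses whose
    onset falls beyond the trial duration are not emitted.
    """
    if cue not in space.cues:
        raise ValueError(f"cue {cue!r} not present in semantic space")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # Pools keep lexicon (eccentricity) order: prototypical words first.
    pools = {m: list(ws) for m, ws in sorted(space.words_for(cue).items())}
    if not any(pools.values()):
        warnings.warn(f"cue {cue!r} has an empty lexicon; returning empty log")
        return _empty_log(), SessionTruth(participant, cue, [], 0, 0)

    rows: list[dict] = []
    kinds: list[str] = []
    n_free = 0
    n_thresh = 0
    irt_sum = 0.0
    n_irt = 0

    def pop_word(meaning: int) -> str:
        # Central-first retrieval with mild stochastic skipping: deeper
        # exploitation reaches increasingly peripheral cluster members.
        pool = pools[meaning]
        j = min(int(rng.geometric(0.6)) - 1, len(pool) - 1)
        return pool.pop(j)

    def meanings_with_words(exclude: int | None = None) -> list[int]:
        return [m for m, ws in pools.items() if ws and m != exclude]

    # First response: enters a random non-empty meaning; its latency from cue
    # onset is not an IRT.
    current = int(rng.choice(meanings_with_words()))
    onset = _lognormal_mean(rng, policy.mu_cluster, policy.noise_sd)
    pos = 1  # position within the current cluster
    if onset > policy.trial_duration:
        return _empty_log(), SessionTruth(participant, cue, [], 0, 0)
    rows.append(dict(participant=participant, cue=cue, response_index=1,
                     word=pop_word(current), onset=onset,
                     offset=onset + ARTICULATION_S, meaning=f"m{current}"))
    kinds.append("initial")

    while True:
        # --- decide the next response ------------------------------------
        threshold_reached = None
        if n_irt == 0:
            kind = "C"  # no marginal-value estimate yet: exploit
        else:
            run_mean = irt_sum / n_irt
            prospective = policy.mu_cluster * policy.ramp ** pos
            threshold_reached = bool(prospective
                                     > policy.threshold_frac * run_mean)
            if threshold_reached:
                kind = "SC" if rng.random() < policy.p_slow_cluster else "S"
            else:
                kind = "FS" if rng.random() < policy.p_fast_switch else "C"

        # --- resolve lexicon exhaustion -----------------------------------
        if kind in ("C", "SC") and not pools[current]:
            kind = "S_forced" if meanings_with_words(exclude=current) else None
        elif kind in ("S", "FS", "S_forced") and not meanings_with_words(exclude=current):
            kind = "C_forced" if pools[current] else None
        if kind is None:
            break  # lexicon exhausted

        # --- draw the IRT and emit ----------------------------------------
        if kind in ("C", "C_forced"):
            irt = _lognormal_mean(rng, policy.mu_cluster * policy.ramp ** pos,
                                  policy.noise_sd)
            meaning, pos = current, pos + 1
        elif kind == "SC":
            irt = (_lognormal_mean(rng, policy.mu_cluster * policy.ramp ** pos,
                                   policy.noise_sd) + policy.switch_cost)
            meaning, pos = current, pos + 1
        elif kind == "FS":
            irt = _lognormal_mean(rng, policy.mu_cluster, policy.noise_sd)
            meaning = int(rng.choice(meanings_with_words(exclude=current)))
            pos = 1
        else:  # "S" or "S_forced"
            irt = (_lognormal_mean(rng, policy.mu_cluster, policy.noise_sd)
                   + policy.switch_cost)
            meaning = int(rng.choice(meanings_with_words(exclude=current)))
            pos = 1

        prev_offset = rows[-1]["offset"]
        onset = prev_offset + irt
        if onset > policy.trial_duration:
            break
        current = meaning
        rows.append(dict(participant=participant, cue=cue,
                         response_index=len(rows) + 1, word=pop_word(current),
                         onset=onset, offset=onset + ARTICULATION_S,
                         meaning=f"m{current}"))
        kinds.append(kind)
        irt_sum += irt
        n_irt += 1
        if threshold_reached is True:
            n_thresh += 1
        elif threshold_reached is False:
            n_free += 1

    return (pd.DataFrame(rows),
            SessionTruth(participant, cue, kinds, n_free, n_thresh))


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["participant", "cue", "response_index",
                                 "word", "onset", "offset", "meaning"])


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityBundle:
    """One subject's symmetric connectivity matrix plus labels and motion."""

    subject: str
    matrix: np.ndarray
    node_labels: dict[int, str]
    motion: float


def _validate_edges(edges: Iterable[tuple[int, int]], n_nodes: int,
                    name: str) -> list[tuple[int, int]]:
    out = []
    for i, j in edges:
        if i == j:
            raise ValueError(f"{name} edge ({i},{j}) lies on the diagonal")
        if not (0 <= i < j < n_nodes):
            raise ValueError(f"{name} edge ({i},{j}) outside strict upper "
                             f"triangle of {n_nodes} nodes")
        out.append((int(i), int(j)))
    return out


def default_node_labels(n_nodes: int,
                        networks: Sequence[str] = DEFAULT_NETWORK_NAMES) -> dict[int, str]:
    """Round-robin assignment of nodes to named functional networks."""
    return {i: networks[i % len(networks)] for i in range(n_nodes)}


def generate_connectivity(
    n_subjects: int,
    n_nodes: int,
    trait: np.ndarray,
    planted_pos: Iterable[tuple[int, int]],
    planted_neg: Iterable[tuple[int, int]],
    beta: float,
    noise_sd: float,
    seed: int | np.random.Generator,
    node_labels: Mapping[int, str] | None = None,
) -> list[ConnectivityBundle]:
    """Symmetric unit-diagonal matrices with trait effects planted on edges.

    Background edges are N(0, noise_sd); each planted positive (negative) edge
    gains ``+beta * z`` (``-beta * z``) where ``z`` is the standardized trait.
    A per-subject motion covariate (mean framewise displacement, mm) is drawn
    independently.
    """
    trait = np.asarray(trait, dtype=float)
    if trait.shape != (n_subjects,):
        raise ValueError("trait must have length n_subjects")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    pos = _validate_edges(planted_pos, n_nodes, "planted_pos")
    neg = _validate_edges(planted_neg, n_nodes, "planted_neg")
    if set(pos) & set(neg):
        raise ValueError("planted positive and negative edge sets overlap")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = trait.std()
    z = (trait - trait.mean()) / sd if sd > 0 else np.zeros_like(trait)
    labels = dict(node_labels) if node_labels is not None else default_node_labels(n_nodes)

    bundles = []
    iu = np.triu_indices(n_nodes, k=1)
    for s in range(n_subjects):
        m = np.zeros((n_nodes, n_nodes))
        m[iu] = rng.normal(0.0, noise_sd, size=len(iu[0]))
        for (i, j) in pos:
            m[i, j] += beta * z[s]
        for (i, j) in neg:
            m[i, j] -= beta * z[s]
        m = m + m.T
        np.fill_diagonal(m, 1.0)
        motion = float(np.exp(rng.normal(np.log(0.15), 0.3)))
        bundles.append(ConnectivityBundle(f"p{s:03d}", m, labels, motion))
    return bundles


# ---------------------------------------------------------------------------
# Mediated latent structure
# ---------------------------------------------------------------------------

def generate_mediation_triple(
    a_true: float,
    b_true: float,
    n: int,
    seed: int | np.random.Generator,
    c_prime_true: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (x, m, y) from the mediated structure the cohort generator uses.

    x ~ N(0,1); m = a*x + sqrt(1-a^2) e1; y = b*m + c'*x + s e2 with s chosen
    so var(y) is ~1.  This is the latent skeleton behind the cohort's
    brain -> search-pattern -> creativity chain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a_true * x + np.sqrt(max(0.0, 1 - a_true**2)) * rng.standard_normal(n)
    resid_var = max(0.05, 1 - b_true**2 - c_prime_true**2
                    - 2 * a_true * b_true * c_prime_true)
    y = b_true * m + c_prime_true * x + np.sqrt(resid_var) * rng.standard_normal(n)
    return x, m, y


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a simulated cohort.

    Defaults mirror the spoken-mode study: 86 participants, 3 polysemous cues,
    1-minute trials, ~15 responses per cue, deviant rates near the observed
    response-type shares (~14% fast switching, ~20% slow clustering).
    """

    n_participants: int = 86
    n_cues: int = 3
    n_meanings: int = 5
    words_per_meaning: int = 12
    dim: int = 50
    within_sd: float = 0.3
    policy: ForagingPolicy = field(default_factory=ForagingPolicy)
    scale_sd: float = 0.2        # lognormal spread of per-participant time scale
    kappa_sd: float = 0.05       # spread of the switch-threshold fraction
    p_fs_slope: float = 0.05     # latent trait -> fast-switch rate
    p_sc_slope: float = 0.05     # latent trait -> slow-cluster rate
    n_nodes: int = 200
    n_planted: int = 10          # edges per sign per trait
    beta: float = 0.3
    edge_noise_sd: float = 0.2
    a_true: float = 0.4          # brain latent -> search-pattern trait
    b_true: float = 0.3          # search-pattern count -> creativity
    c_prime_true: float = 0.1    # direct brain -> creativity effect
    exec_slope: float = 0.3      # slow-switch count -> executive scores

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_cues < 1:
            raise ValueError("n_cues must be >= 1")
        if self.n_nodes < 3:
            raise ValueError("n_nodes must be >= 3")
        needed = 4 * self.n_planted
        if needed > self.n_nodes * (self.n_nodes - 1) // 2:
            raise ValueError("not enough edges for the planted sets")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    policies: pd.DataFrame           # per-participant policy parameters
    traits: pd.DataFrame             # latent u_fs, u_sc, m_fs, m_sc
    true_counts: pd.DataFrame        # per-participant true event counts
    planted: dict[str, list[tuple[int, int]]]
    beta: float
    a_true: float
    b_true: float
    c_prime_true: float

    def to_json(self) -> str:
        payload = {
            "beta": self.beta,
            "a_true": self.a_true,
            "b_true": self.b_true,
            "c_prime_true": self.c_prime_true,
            "planted": {k: [list(e) for e in v] for k, v in self.planted.items()},
            "policies": self.policies.to_dict(orient="list"),
            "traits": self.traits.to_dict(orient="list"),
            "true_counts": self.true_counts.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1)


@dataclass
class Cohort:
    """A complete synthetic dataset: logs, space, brains, covariates, truth."""

    logs: pd.DataFrame
    space: SemanticSpace
    bundles: list[ConnectivityBundle]
    covariates: pd.DataFrame
    truth: GroundTruth
    session_truths: list[SessionTruth]


def _sample_disjoint_edges(rng: np.random.Generator, n_nodes: int,
                           n_sets: int, per_set: int) -> list[list[tuple[int, int]]]:
    iu = np.triu_indices(n_nodes, k=1)
    all_edges = list(zip(iu[0].tolist(), iu[1].tolist()))
    chosen = rng.choice(len(all_edges), size=n_sets * per_set, replace=False)
    sets = []
    for k in range(n_sets):
        sets.append([all_edges[i] for i in chosen[k * per_set:(k + 1) * per_set]])
    return sets


def generate_cohort(config: CohortConfig, seed: int) -> Cohort:
    """Generate a full cohort under the mediated ground-truth structure.

    Latent brain factors u_fs, u_sc drive planted connectivity edges; the
    search-pattern traits m_fs = a*u + noise set each participant's deviant
    rates; creativity scores are built from the *true* deviant counts (CAT_CR
    from fast switches, AUT scores from slow clustering), closing the
    brain -> behavior -> creativity mediation chain.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    r_space, r_traits, r_sessions, r_brain, r_scores = \
        [np.random.default_rng(s) for s in ss.spawn(5)]
    n = config.n_participants

    space = generate_semantic_space(
        config.n_cues, config.n_meanings, config.words_per_meaning,
        config.dim, config.within_sd, seed=r_space)

    # --- latent traits and per-participant policies -----------------------
    u_fs = r_traits.standard_normal(n)
    u_sc = r_traits.standard_normal(n)
    a = config.a_true
    m_fs = a * u_fs + np.sqrt(max(0.0, 1 - a * a)) * r_traits.standard_normal(n)
    m_sc = a * u_sc + np.sqrt(max(0.0, 1 - a * a)) * r_traits.standard_normal(n)
    scale = np.exp(r_traits.normal(0.0, config.scale_sd, size=n))
    kappa = np.clip(config.policy.threshold_frac
                    + r_traits.normal(0.0, config.kappa_sd, size=n), 0.6, 0.98)
    p_fs = np.clip(config.policy.p_fast_switch + config.p_fs_slope * m_fs, 0.0, 0.6)
    p_sc = np.clip(config.policy.p_slow_cluster + config.p_sc_slope * m_sc, 0.0, 0.6)

    participants = [f"p{i:03d}" for i in range(n)]
    policies = []
    logs = []
    session_truths: list[SessionTruth] = []
    counts = {"fast_switch": [], "slow_cluster": [], "slow_switch": [],
              "n_free": [], "n_thresh": []}
    for i, pid in enumerate(participants):
        pol = replace(config.policy.scaled(scale[i]),
                      p_fast_switch=float(p_fs[i]), p_slow_cluster=float(p_sc[i]),
                      threshold_frac=float(kappa[i]))
        policies.append(dict(participant=pid, mu_cluster=pol.mu_cluster,
                             switch_cost=pol.switch_cost,
                             p_fast_switch=pol.p_fast_switch,
                             p_slow_cluster=pol.p_slow_cluster,
                             threshold_frac=pol.threshold_frac))
        c_fs = c_sc = c_ss = c_free = c_thr = 0
        for cue in space.cues:
            log, truth = generate_fluency_session(space, pol, cue, r_sessions,
                                                  participant=pid)
            logs.append(log)
            session_truths.append(truth)
            c_fs += truth.n_fast_switch
            c_sc += truth.n_slow_cluster
            c_ss += sum(k in ("S", "S_forced") for k in truth.kinds)
            c_free += truth.n_free_decisions
            c_thr += truth.n_threshold_decisions
        counts["fast_switch"].append(c_fs)
        counts["slow_cluster"].append(c_sc)
        counts["slow_switch"].append(c_ss)
        counts["n_free"].append(c_free)
        counts["n_thresh"].append(c_thr)

    logs_df = pd.concat([l for l in logs if len(l)], ignore_index=True)
    true_counts = pd.DataFrame({"participant": participants, **counts})

    # --- connectivity with planted effects for both traits ----------------
    fs_pos, fs_neg, sc_pos, sc_neg = _sample_disjoint_edges(
        r_brain, config.n_nodes, 4, config.n_planted)
    labels = default_node_labels(config.n_nodes)
    iu = np.triu_indices(config.n_nodes, k=1)
    z_fs = (u_fs - u_fs.mean()) / u_fs.std()
    z_sc = (u_sc - u_sc.mean()) / u_sc.std()
    bundles = []
    for s, pid in enumerate(participants):
        m = np.zeros((config.n_nodes, config.n_nodes))
        m[iu] = r_brain.normal(0.0, config.edge_noise_sd, size=len(iu[0]))
        for (i, j) in fs_pos:
            m[i, j] += config.beta * z_fs[s]
        for (i, j) in fs_neg:
            m[i, j] -= config.beta * z_fs[s]
        for (i, j) in sc_pos:
            m[i, j] += config.beta * z_sc[s]
        for (i, j) in sc_neg:
            m[i, j] -= config.beta * z_sc[s]
        m = m + m.T
        np.fill_diagonal(m, 1.0)
        motion = float(np.exp(r_brain.normal(np.log(0.15), 0.3)))
        bundles.append(ConnectivityBundle(pid, m, labels, motion))

    # --- creativity and executive scores (mediated structure) -------------
    def zs(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v, dtype=float)

    x_fs = np.array([sum(b.matrix[i, j] for (i, j) in fs_pos) for b in bundles])
    x_sc = np.array([sum(b.matrix[i, j] for (i, j) in sc_pos) for b in bundles])
    b_t, cp = config.b_true, config.c_prime_true
    resid_sd = np.sqrt(max(0.05, 1 - b_t**2 - cp**2 - 2 * a * b_t * cp))

    def outcome(count: np.ndarray, x: np.ndarray) -> np.ndarray:
        return (b_t * zs(count) + cp * zs(x)
                + resid_sd * r_scores.standard_normal(n))

    cat_cr = np.clip(60 + 10 * outcome(true_counts["fast_switch"].to_numpy(float), x_fs), 0, 100)
    aut_flu = 25 + 8 * outcome(true_counts["slow_cluster"].to_numpy(float), x_sc)
    aut_unique = 8 + 4 * outcome(true_counts["slow_cluster"].to_numpy(float), x_sc)
    z_ss = zs(true_counts["slow_switch"].to_numpy(float))
    e = config.exec_slope
    noise = lambda: np.sqrt(1 - e * e) * r_scores.standard_normal(n)
    covariates = pd.DataFrame({
        "participant": participants,
        "motion": [b.motion for b in bundles],
        "CAT_CR": cat_cr,
        "AUT_fluency": aut_flu,
        "AUT_uniqueness": aut_unique,
        "Backward_span": 8 + 2 * (e * z_ss + noise()),
        "TMT_shifting": 45 - 15 * (e * z_ss + noise()),
        "Stroop_interference": 18 - 8 * (e * z_ss + noise()),
    })

    truth = GroundTruth(
        policies=pd.DataFrame(policies),
        traits=pd.DataFrame({"participant": participants, "u_fs": u_fs,
                             "u_sc": u_sc, "m_fs": m_fs, "m_sc": m_sc}),
        true_counts=true_counts,
        planted={"fs_pos": fs_pos, "fs_neg": fs_neg,
                 "sc_pos": sc_pos, "sc_neg": sc_neg},
        beta=config.beta, a_true=config.a_true, b_true=config.b_true,
        c_prime_true=config.c_prime_true,
    )
    return Cohort(logs_df, space, bundles, covariates, truth, session_truths)
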