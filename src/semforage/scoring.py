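"""Score fluency response logs into per-response and per-participant
foraging measures.

The scoring chain computes, for each response:

* IRT — inter-response time (end of previous response to start of the next
  in spoken mode; validation-to-first-keypress plus a thinking-time
  correction in typed mode);
* IRS — cosine similarity between embedding vectors of consecutive words;
* transition — initial / clustering (same meaning as predecessor) /
  switching (different meaning);
* IRTr, IRSr — the ratios of IRT and IRS to the participant's per-cue
  marginal (mean) value;
* speed — fast (IRTr < 1) or slow (IRTr >= 1);
* switch-relative positions (−2, −1, S, +1, +2) anchored at each switch.

Per-participant summaries aggregate response level -> cue -> participant.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, NumericError
from .synthetic import SemanticSpace

__all__ = [
    "compute_irt",
    "label_transitions",
    "compute_irs",
    "marginal_values",
    "compute_ratios",
    "classify_speed",
    "align_positions",
    "summarize_participant",
    "score",
    "ScoredBundle",
]

KEY = ["participant", "cue", "response_index"]
IRSR_EPSILON = 1e-6  # |marginal IRS| below this leaves IRSr undefined


def _sorted(log: pd.DataFrame) -> pd.DataFrame:
    return log.sort_values(KEY, kind="stable").reset_index(drop=True)


def compute_irt(log: pd.DataFrame, mode: str = "spoken") -> pd.DataFrame:
    """Add an ``irt`` column (seconds; NaN where undefined).

    Spoken mode: ``irt_k = onset_k - offset_{k-1}`` within each cue; the first
    response of a cue has no IRT.  Typed mode: raw IRT is validation-to-first-
    keypress (trial start for the first response), plus thinking time
    ``max(0, measured_typing - n_chars / fastest_speed)`` where the fastest
    typing speed is the participant's maximum chars-per-second over responses
    longer than four characters.
    """
    if mode not in ("spoken", "typed"):
        raise ValueError("mode must be 'spoken' or 'typed'")
    df = _sorted(log).copy()
    if mode == "spoken":
        for col in ("onset", "offset"):
            if col not in df.columns:
                raise FormatError(f"spoken mode requires column {col!r}")
        prev_offset = df.groupby(["participant", "cue"])["offset"].shift(1)
        df["irt"] = df["onset"] - prev_offset
    else:
        for col in ("first_keypress", "validation", "n_chars"):
            if col not in df.columns:
                raise FormatError(f"typed mode requires column {col!r}")
        grp = df.groupby(["participant", "cue"])
        prev_validation = grp["validation"].shift(1).fillna(0.0)
        raw = df["first_keypress"] - prev_validation
        measured = df["validation"] - df["first_keypress"]
        cps = df["n_chars"] / measured.replace(0.0, np.nan)
        fastest = (cps.where(df["n_chars"] > 4)
                   .groupby(df["participant"]).transform("max"))
        theoretical = df["n_chars"] / fastest
        thinking = (measured - theoretical).clip(lower=0.0).fillna(0.0)
        df["irt"] = raw + thinking
    bad = df.index[df["irt"] < 0]
    if len(bad):
        r = df.loc[bad[0]]
        raise DataError(
            f"negative IRT for participant={r['participant']} cue={r['cue']} "
            f"response_index={r['response_index']}")
    return df


def label_transitions(log: pd.DataFrame) -> pd.DataFrame:
    """Add a ``transition`` column: initial / clustering / switching."""
    df = _sorted(log).copy()
    if df["meaning"].isna().any():
        r = df[df["meaning"].isna()].iloc[0]
        raise DataError(f"missing meaning label for participant="
                        f"{r['participant']} cue={r['cue']} "
                        f"response_index={r['response_index']}")
    prev = df.groupby(["participant", "cue"])["meaning"].shift(1)
    df["transition"] = np.where(prev.isna(), "initial",
                                np.where(df["meaning"] == prev,
                                         "clustering", "switching"))
    return df


def _as_embedding_table(embeddings) -> Mapping[str, np.ndarray]:
    if isinstance(embeddings, SemanticSpace):
        return embeddings.embeddings
    return embeddings


def compute_irs(log: pd.DataFrame, embeddings) -> pd.DataFrame:
    """Add an ``irs`` column: cosine similarity of consecutive words.

    Undefined (NaN) for the first response of each cue and whenever either
    word lacks an embedding; the number of misses is stored in
    ``df.attrs['irs_missing']`` and reported as a warning.
    """
    table = _as_embedding_table(embeddings)
    df = _sorted(log).copy()
    norms: dict[str, float] = {}

    def vec(word):
        v = table.get(word)
        if v is None:
            return None
        if word not in norms:
            n = float(np.linalg.norm(v))
            if n == 0.0:
                raise NumericError(f"zero-norm embedding for word {word!r}")
            norms[word] = n
        return v

    prev_word = df.groupby(["participant", "cue"])["word"].shift(1)
    irs = np.full(len(df), np.nan)
    misses = 0
    for i, (w1, w2) in enumerate(zip(prev_word, df["word"])):
        if pd.isna(w1):
            continue
        v1, v2 = vec(w1), vec(w2)
        if v1 is None or v2 is None:
            misses += 1
            continue
        irs[i] = float(np.dot(v1, v2) / (norms[w1] * norms[w2]))
    df["irs"] = irs
    df.attrs["irs_missing"] = misses
    if misses:
        warnings.warn(f"{misses} consecutive pairs skipped: word(s) without "
                      f"embedding")
    return df


def marginal_values(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, cue) marginal IRT/IRS and per-participant long-term
    values.

    The per-cue marginal is the arithmetic mean of that cue's defined IRTs
    (resp. IRSs); the long-term value is the mean of the per-cue marginals
    (cue-level averaging, consistent with the response -> cue -> participant
    order used throughout).  Cues with no defined IRT are dropped with a
    warning.
    """
    scored = scored if "irs" in scored.columns else scored.assign(irs=np.nan)
    g = scored.groupby(["participant", "cue"])
    out = g.agg(marginal_irt=("irt", "mean"),
                marginal_irs=("irs", "mean"),
                n_irt=("irt", "count")).reset_index()
    empty = out[out["n_irt"] == 0]
    if len(empty):
        warnings.warn(f"{len(empty)} cue(s) with no defined IRT dropped from "
                      f"marginal values")
        out = out[out["n_irt"] > 0].copy()
    lt = (out.groupby("participant")[["marginal_irt", "marginal_irs"]]
          .mean().rename(columns={"marginal_irt": "long_term_irt",
                                  "marginal_irs": "long_term_irs"}))
    return out.merge(lt, on="participant").drop(columns="n_irt")


def compute_ratios(scored: pd.DataFrame,
                   marginals: pd.DataFrame | None = None,
                   epsilon: float = IRSR_EPSILON) -> pd.DataFrame:
    """Add ``irtr`` and ``irsr``: each response's IRT/IRS divided by the
    per-cue marginal value.  IRSr is undefined when the cue's marginal IRS is
    within ``epsilon`` of zero."""
    if "irs" not in scored.columns:
        scored = scored.assign(irs=np.nan)
    if marginals is None:
        marginals = marginal_values(scored)
    df = scored.merge(
        marginals[["participant", "cue", "marginal_irt", "marginal_irs"]],
        on=["participant", "cue"], how="left")
    bad = df[(df["marginal_irt"] <= 0) & df["irt"].notna()]
    if len(bad):
        r = bad.iloc[0]
        raise DataError(f"non-positive marginal IRT for participant="
                        f"{r['participant']} cue={r['cue']}")
    df["irtr"] = df["irt"] / df["marginal_irt"]
    safe = df["marginal_irs"].abs() > epsilon
    df["irsr"] = np.where(safe & df["irs"].notna(),
                          df["irs"] / df["marginal_irs"], np.nan)
    return df


def classify_speed(scored: pd.DataFrame) -> pd.DataFrame:
    """Add ``speed``: fast (IRTr < 1) / slow (IRTr >= 1); the boundary value
    1 is classified slow so the fast/slow partition is exhaustive."""
    df = scored.copy()
    df["speed"] = np.where(df["irtr"].isna(), None,
                           np.where(df["irtr"] < 1.0, "fast", "slow"))
    return df


def align_positions(scored: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Anchor switch-relative positions.

    For each switching response S, the up-to-two clustering responses
    immediately before it (same cue) receive positions −2, −1 and the
    up-to-two clustering responses immediately after it (before any further
    switch) receive +1, +2.  A clustering response between two nearby switches
    can serve both as +k of the earlier switch and −k of the later one; all
    roles are kept in the returned anchor table.

    Returns ``(scored, anchors)`` where ``scored`` gains a ``position``
    column (roles joined by ';', 'none' when absent) and a
    ``switch_speed_context`` column (speed of the governing switch for the
    primary role), and ``anchors`` has one row per (switch, position) pair.
    """
    df = _sorted(scored).copy()
    if "transition" not in df.columns:
        raise DataError("transitions must be labeled before aligning positions")
    anchors: list[dict] = []
    for (pid, cue), g in df.groupby(["participant", "cue"], sort=False):
        idx = g.index.to_numpy()
        trans = g["transition"].to_numpy()
        speeds = g["speed"].to_numpy() if "speed" in g else np.full(len(g), None)
        switch_positions = np.nonzero(trans == "switching")[0]
        for s in switch_positions:
            sw_speed = speeds[s]
            anchors.append(dict(participant=pid, cue=cue, switch_row=int(idx[s]),
                                position="S", row=int(idx[s]),
                                switch_speed=sw_speed))
            for off, label in ((-1, "-1"), (-2, "-2")):
                k = s + off
                if k >= 0 and all(trans[j] == "clustering" for j in range(k, s)) \
                        and trans[k] == "clustering":
                    anchors.append(dict(participant=pid, cue=cue,
                                        switch_row=int(idx[s]), position=label,
                                        row=int(idx[k]), switch_speed=sw_speed))
            for off, label in ((1, "+1"), (2, "+2")):
                k = s + off
                if k < len(trans) and all(trans[j] == "clustering"
                                          for j in range(s + 1, k + 1)):
                    anchors.append(dict(participant=pid, cue=cue,
                                        switch_row=int(idx[s]), position=label,
                                        row=int(idx[k]), switch_speed=sw_speed))
    anchors_df = pd.DataFrame(anchors, columns=["participant", "cue",
                                                "switch_row", "position",
                                                "row", "switch_speed"])
    roles = anchors_df.groupby("row")["position"].agg(";".join) \
        if len(anchors_df) else pd.Series(dtype=object)
    ctx = anchors_df.groupby("row")["switch_speed"].first() \
        if len(anchors_df) else pd.Series(dtype=object)
    df["position"] = df.index.map(roles).fillna("none")
    df["switch_speed_context"] = df.index.map(ctx)
    return df, anchors_df


def summarize_participant(scored: pd.DataFrame,
                          anchors: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-participant aggregates (one row per participant).

    Fluency is the mean over cues of the number of case-folded unique words;
    IRT/IRS/IRTr/IRSr means by transition type are averaged response -> cue ->
    participant; the four fast/slow x clustering/switching counts partition the
    non-initial responses with defined IRT; pre-switch IRT is the mean IRT of
    position −1 responses.  Participants with zero switches have undefined
    pre-switch fields and are flagged.
    """
    if anchors is None:
        scored, anchors = align_positions(scored)
    df = scored
    rows = []
    marg = marginal_values(df).groupby("participant")[
        ["long_term_irt", "long_term_irs"]].first()
    for pid, g in df.groupby("participant", sort=True):
        rec: dict = {"participant": pid}
        rec["polyft_fluency"] = float(
            g.groupby("cue")["word"].apply(lambda w: w.str.casefold().nunique())
            .mean())
        rec["long_term_irt"] = float(marg.loc[pid, "long_term_irt"])
        rec["long_term_irs"] = float(marg.loc[pid, "long_term_irs"])

        # cue-then-participant means per transition type
        for trans in ("clustering", "switching"):
            sub = g[g["transition"] == trans]
            for metric in ("irt", "irs", "irtr", "irsr"):
                by_cue = sub.groupby("cue")[metric].mean()
                rec[f"{trans}_{metric}"] = float(by_cue.mean()) \
                    if by_cue.notna().any() else np.nan

        labeled = g[(g["transition"] != "initial") & g["irt"].notna()]
        n_labeled = len(labeled)
        for speed in ("fast", "slow"):
            for trans in ("clustering", "switching"):
                n = int(((labeled["speed"] == speed)
                         & (labeled["transition"] == trans)).sum())
                rec[f"n_{speed}_{trans}"] = n
                rec[f"pct_{speed}_{trans}"] = 100.0 * n / n_labeled \
                    if n_labeled else np.nan
        rec["n_labeled"] = n_labeled
        rec["n_switches"] = int((g["transition"] == "switching").sum())

        pre = anchors[(anchors["participant"] == pid)
                      & (anchors["position"] == "-1")]
        if len(pre):
            irts = df.loc[pre["row"], "irt"]
            by_cue = irts.groupby(pre["cue"].to_numpy()).mean()
            rec["pre_switch_irt"] = float(by_cue.mean())
            rec["pre_switch_gap"] = abs(rec["pre_switch_irt"]
                                        - rec["long_term_irt"])
        else:
            rec["pre_switch_irt"] = np.nan
            rec["pre_switch_gap"] = np.nan
        rec["flagged_no_switch"] = rec["n_switches"] == 0
        rows.append(rec)
    return pd.DataFrame(rows)


class ScoredBundle:
    """Result of the full scoring chain: per-response table, per-cue
    marginals, switch-anchored positions, and per-participant summaries."""

    def __init__(self, scored: pd.DataFrame, marginals: pd.DataFrame,
                 anchors: pd.DataFrame, summaries: pd.DataFrame):
        self.scored = scored
        self.marginals = marginals
        self.anchors = anchors
        self.summaries = summaries


def score(log: pd.DataFrame, embeddings=None, mode: str = "spoken") -> ScoredBundle:
    """Run the full scoring chain on a response log."""
    df = compute_irt(log, mode=mode)
    df = label_transitions(df)
    if embeddings is not None:
        df = compute_irs(df, embeddings)
    else:
        df["irs"] = np.nan
    marginals = marginal_values(df)
    df = compute_ratios(df, marginals)
    df = classify_speed(df)
    df, anchors = align_positions(df)
    summaries = summarize_participant(df, anchors)
    return ScoredBundle(df, marginals, anchors, summaries)
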