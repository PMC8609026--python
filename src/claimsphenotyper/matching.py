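"""Coarsened exact matching (CEM) with k-to-k pruning and L1 imbalance.

CEM coarsens each matching covariate (exact for categoricals, explicit bin
edges for numerics), groups cases and controls into strata sharing an
identical coarsened signature, and discards cases in strata with no controls.
The k2k variant additionally reduces each stratum to a 1:1 match by randomly
selecting min(n_cases, n_controls) units from each side, so every retained
case is paired with exactly one control from its own stratum.

Balance is summarized by the multivariate L1 imbalance: half the summed
absolute difference of the two groups' relative frequencies over the joint
signature bins. 0.0 means perfectly matched distributions, 1.0 completely
disjoint ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_AGE_EDGES_YEARS = (0.0, 1.0, 5.0, 12.0, 19.0)


@dataclass
class CoarseningScheme:
    """Per-covariate coarsening rule: ``None`` = categorical (exact),
    otherwise strictly increasing numeric bin edges (half-open bins)."""

    rules: dict[str, Optional[Sequence[float]]]

    def __post_init__(self) -> None:
        for covariate, edges in self.rules.items():
            if edges is None:
                continue
            edges = tuple(float(e) for e in edges)
            if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(
                    f"bin edges for {covariate!r} must be strictly increasing "
                    f"with >=2 edges, got {edges}")
            self.rules[covariate] = edges

    @property
    def covariates(self) -> list[str]:
        return list(self.rules)

    @classmethod
    def default(cls, pediatric: bool = True) -> "CoarseningScheme":
        """Study default: exact on demographics and birth year; age at index
        (years) binned 0-1, 1-5, 5-12, 12-19 for the pediatric population."""
        rules: dict[str, Optional[Sequence[float]]] = {
            "race_ethnicity": None,
            "sex": None,
            "census_division": None,
            "birth_year": None,
            "household_children": None,
        }
        if pediatric:
            rules["age_years"] = DEFAULT_AGE_EDGES_YEARS
        return cls(rules)


def _bin_index(value: float, edges: Sequence[float], covariate: str) -> int:
    """Half-open binning [edges[i], edges[i+1]); out-of-range values clamp to
    the boundary bin (logged)."""
    n_bins = len(edges) - 1
    idx = int(np.digitize(value, edges, right=False)) - 1
    if idx < 0 or idx > n_bins - 1:
        logger.warning("value %s of %r outside bin edges %s; assigned boundary bin",
                       value, covariate, edges)
    return min(max(idx, 0), n_bins - 1)


def coarsen(units: pd.DataFrame, scheme: CoarseningScheme) -> list[tuple]:
    """Coarsened signature (tuple) per unit, in row order."""
    for covariate in scheme.covariates:
        if covariate not in units.columns:
            raise ValueError(f"missing covariate column {covariate!r}")
        if units[covariate].isna().any():
            raise ValueError(f"missing values in covariate {covariate!r}")
    signatures = []
    for row in units[scheme.covariates].itertuples(index=False, name=None):
        signature = []
        for value, covariate in zip(row, scheme.covariates):
            edges = scheme.rules[covariate]
            signature.append(value if edges is None
                             else _bin_index(float(value), edges, covariate))
        signatures.append(tuple(signature))
    return signatures


def l1_imbalance(cases: pd.DataFrame, controls: pd.DataFrame,
                 scheme: CoarseningScheme) -> float:
    """Multivariate L1 imbalance over joint coarsened bins, in [0, 1]."""
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("l1_imbalance requires both groups non-empty")
    case_counts = pd.Series(coarsen(cases, scheme)).value_counts(normalize=True)
    control_counts = pd.Series(coarsen(controls, scheme)).value_counts(normalize=True)
    joined = pd.concat([case_counts, control_counts], axis=1).fillna(0.0)
    value = 0.5 * (joined.iloc[:, 0] - joined.iloc[:, 1]).abs().sum()
    return float(min(1.0, max(0.0, value)))  # clamp float-summation spill


@dataclass
class MatchResult:
    pairs: list[tuple[str, str]]            # (case_id, control_id), 1:1
    pruned_cases: list[str]                 # cases in strata with no control
    pre_l1: float
    post_l1: Optional[float]                # None when nothing was matched
    stratum_counts: dict[tuple, tuple[int, int, int]] = field(default_factory=dict)
    # signature -> (n_cases, n_controls, n_pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "control_id"])


def cem_match_k2k(cases: pd.DataFrame, controls: pd.DataFrame,
                  scheme: CoarseningScheme, seed: int,
                  id_column: str = "patient_id") -> MatchResult:
    """k-to-k CEM: within each shared stratum pair min(n_cases, n_controls)
    randomly selected units; deterministic for a fixed seed."""
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("cem_match_k2k requires both groups non-empty")
    rng = np.random.default_rng(seed)
    pre_l1 = l1_imbalance(cases, controls, scheme)

    case_sigs = coarsen(cases, scheme)
    control_sigs = coarsen(controls, scheme)
    by_sig_cases: dict[tuple, list[str]] = {}
    for pid, sig in zip(cases[id_column].astype(str), case_sigs):
        by_sig_cases.setdefault(sig, []).append(pid)
    by_sig_controls: dict[tuple, list[str]] = {}
    for pid, sig in zip(controls[id_column].astype(str), control_sigs):
        by_sig_controls.setdefault(sig, []).append(pid)

    pairs: list[tuple[str, str]] = []
    pruned: list[str] = []
    stratum_counts: dict[tuple, tuple[int, int, int]] = {}
    for sig in sorted(by_sig_cases, key=repr):
        case_ids = sorted(by_sig_cases[sig])
        control_ids = sorted(by_sig_controls.get(sig, []))
        k = min(len(case_ids), len(control_ids))
        stratum_counts[sig] = (len(case_ids), len(control_ids), k)
        if k == 0:
            pruned.extend(case_ids)
            continue
        chosen_cases = [case_ids[i] for i in rng.permutation(len(case_ids))[:k]]
        chosen_controls = [control_ids[i]
                           for i in rng.permutation(len(control_ids))[:k]]
        pairs.extend(zip(chosen_cases, chosen_controls))

    post_l1 = None
    if pairs:
        matched_case_ids = {c for c, _ in pairs}
        matched_control_ids = {c for _, c in pairs}
        post_l1 = l1_imbalance(
            cases[cases[id_column].astype(str).isin(matched_case_ids)],
            controls[controls[id_column].astype(str).isin(matched_control_ids)],
            scheme)
    return MatchResult(pairs, pruned, pre_l1, post_l1, stratum_counts)


def covariate_frame(assignments: pd.DataFrame, patients: pd.DataFrame,
                    include_age: bool = True) -> pd.DataFrame:
    """Join demographics onto an index frame and derive age at index in years."""
    frame = assignments.merge(patients, on="patient_id", how="left")
    if include_age:
        frame["age_years"] = frame["index_day"].astype(float) / 365.0
    return frame
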