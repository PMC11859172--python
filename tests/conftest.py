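"""Shared fixtures: small seeded cohorts and classification results.

The expensive end-to-end classification of the default synthetic cohort
is computed once per session and shared by the pipeline-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from mdtwpose import WeightVector, generate_cohort
from mdtwpose.classify import channel_distance_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """A compact separable cohort for fast structural tests."""
    return generate_cohort(
        n_subjects=4, n_novel=1, trials_per_class=2, queries_per_class=1, master_seed=11
    )


@dataclass
class CohortRun:
    cohort: object
    labels: list
    build_combined: np.ndarray  # (Q, K) combined distances, build queries
    novel_combined: np.ndarray
    sequence_combined: np.ndarray

    def predictions(self, which: str) -> tuple[list, list]:
        comb = getattr(self, f"{which}_combined")
        queries = getattr(self.cohort, f"{which}_queries")
        preds = [self.labels[int(np.argmin(row))] for row in comb]
        return [q.label for q in queries], preds


@pytest.fixture(scope="session")
def cohort_run():
    """Default-scale cohort classified end-to-end at the operating point."""
    cohort = generate_cohort(master_seed=1)
    lib = cohort.library
    w = WeightVector.tuned().as_array()
    out = {}
    for which in ("build", "novel", "sequence"):
        queries = getattr(cohort, f"{which}_queries")
        out[which] = channel_distance_matrix(lib, queries, 50) @ w
    return CohortRun(
        cohort=cohort,
        labels=lib.labels,
        build_combined=out["build"],
        novel_combined=out["novel"],
        sequence_combined=out["sequence"],
    )
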