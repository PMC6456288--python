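"""Seeded generator of feature tables with planted relevance structure.

The generator emulates the data regime the selector targets — many features,
few instances, a binary phenotype — with four explicitly labelled feature
groups:

* ``informative``: class-conditional Gaussians, N(0,1) for one class and
  N(d,1) for the other, with mean shift ``effect_size`` d (default 2.0, the
  scale of a strongly differentially-expressed marker);
* ``exact_duplicate``: verbatim copies of informative parents (cycled);
* ``noisy_duplicate``: informative parent plus N(0, noise_sd) noise
  (default sd 0.1 — probe-level measurement jitter);
* ``irrelevant``: N(0,1) draws independent of the class.

Ground-truth group membership (and the parent of each duplicate) is
returned alongside the table, so every selector behaviour — irrelevance
filtering, duplicate elimination, retention of weakly correlated features —
is testable without external datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FeatureTable

__all__ = ["SynthSpec", "generate"]


@dataclass(frozen=True)
class SynthSpec:
    n_instances: int = 200
    n_informative: int = 3
    n_exact_duplicates: int = 2
    n_noisy_duplicates: int = 0
    n_irrelevant: int = 5
    class_balance: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_informative,
            self.n_exact_duplicates,
            self.n_noisy_duplicates,
            self.n_irrelevant,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be >= 0")
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if (
            self.n_exact_duplicates + self.n_noisy_duplicates > 0
            and self.n_informative == 0
        ):
            raise ValueError("duplicates require at least one informative feature")
        if self.n_instances < 4:
            raise ValueError("n_instances must be >= 4")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be strictly between 0 and 1")
        n_pos = round(self.n_instances * self.class_balance)
        if n_pos < 1 or n_pos > self.n_instances - 1:
            raise ValueError("class_balance leaves a class empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_features(self) -> int:
        return (
            self.n_informative
            + self.n_exact_duplicates
            + self.n_noisy_duplicates
            + self.n_irrelevant
        )


def generate(spec: SynthSpec) -> tuple[FeatureTable, dict]:
    """Draw one table from ``spec``.  Fully reproducible from ``spec.seed``.

    Returns ``(table, truth)`` where ``truth`` maps each feature id to
    ``{"group": ..., "parent": ...}`` (parent is None except for
    duplicates).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    n_pos = round(n * spec.class_balance)
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    labels = np.where(y == 1, "case", "control")

    columns: list[np.ndarray] = []
    ids: list[str] = []
    truth: dict[str, dict] = {}

    informative = []
    for k in range(spec.n_informative):
        col = rng.normal(0.0, 1.0, n) + spec.effect_size * y
        informative.append(col)
        fid = f"inf_{k}"
        columns.append(col)
        ids.append(fid)
        truth[fid] = {"group": "informative", "parent": None}
    for k in range(spec.n_exact_duplicates):
        parent = k % spec.n_informative
        fid = f"dup_{k}"
        columns.append(informative[parent].copy())
        ids.append(fid)
        truth[fid] = {"group": "exact_duplicate", "parent": f"inf_{parent}"}
    for k in range(spec.n_noisy_duplicates):
        parent = k % spec.n_informative
        fid = f"noisy_{k}"
        columns.append(informative[parent] + rng.normal(0.0, spec.noise_sd, n))
        ids.append(fid)
        truth[fid] = {"group": "noisy_duplicate", "parent": f"inf_{parent}"}
    for k in range(spec.n_irrelevant):
        fid = f"irr_{k}"
        columns.append(rng.normal(0.0, 1.0, n))
        ids.append(fid)
        truth[fid] = {"group": "irrelevant", "parent": None}

    table = FeatureTable(np.column_stack(columns), ids, labels)
    return table, truth
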