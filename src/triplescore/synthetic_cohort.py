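"""Synthetic cohorts with genotype-conditional marker distributions.

Real cohorts of multiple-primary/familial melanoma patients are small, so
downstream code (scoring, evaluation, bootstrapping) is exercised on
generated cohorts of arbitrary size.  The generator draws each marker
independently from a per-genotype categorical distribution on the integer
percent grid -- the same discrete structure the reference cohort exhibits
(p16 concentrated on {0, 50}, all markers on a multiple-of-5 grid).
Within-genotype marker correlation (e.g. between p16 loss and Ki67) is
deliberately not modelled.

Reproducibility contract: one root seed per config; generation derives one
child random stream per genotype via ``numpy.random.SeedSequence.spawn`` in
the fixed genotype order of :class:`~triplescore.cohort_io.Cdkn2aStatus`, so
the draws for one genotype do not depend on the counts requested for the
others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Union

import numpy as np

from .cohort_io import Cdkn2aStatus, Cohort, CohortValidationError, PatientRecord, Split

__all__ = ["SyntheticConfig", "empirical_config", "generate", "split_cohort"]

MARKERS = ("p16", "cd8", "ki67")

#: categorical distribution: (support values, probabilities)
Categorical = tuple[tuple[int, ...], tuple[float, ...]]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class SyntheticConfig:
    """Genotype-conditional categorical marker distributions plus counts.

    ``marker_distributions`` maps ``(status, marker)`` to a categorical
    distribution over integer percentages; every status with a positive
    requested count must have a distribution for all three markers.
    """

    n_per_status: Mapping[Cdkn2aStatus, int]
    marker_distributions: Mapping[tuple[Cdkn2aStatus, str], Categorical]
    seed: int = 0

    def __post_init__(self) -> None:
        for status, count in self.n_per_status.items():
            if not isinstance(status, Cdkn2aStatus) or int(count) < 0:
                raise CohortValidationError(
                    f"invalid status count: {status!r} -> {count!r}"
                )
        for (status, marker), (values, probs) in self.marker_distributions.items():
            if marker not in MARKERS:
                raise CohortValidationError(f"unknown marker {marker!r}")
            values = np.asarray(values)
            probs = np.asarray(probs, dtype=float)
            if values.shape != probs.shape or values.size == 0:
                raise CohortValidationError(
                    f"({status.value}, {marker}): support/probability shape mismatch"
                )
            if np.any(values != values.astype(int)) or np.any(
                (values < 0) | (values > 100)
            ):
                raise CohortValidationError(
                    f"({status.value}, {marker}): support must be integers in [0, 100]"
                )
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > _PROB_TOL:
                raise CohortValidationError(
                    f"({status.value}, {marker}): probabilities must be "
                    "non-negative and sum to 1"
                )
        for status, count in self.n_per_status.items():
            if int(count) > 0:
                for marker in MARKERS:
                    if (status, marker) not in self.marker_distributions:
                        raise CohortValidationError(
                            f"no distribution for ({status.value}, {marker})"
                        )

    def to_json(self, destination: Union[str, Path, IO[str], None] = None) -> str:
        """Serialise to JSON (returned; also written if a destination given)."""
        payload = {
            "seed": int(self.seed),
            "n_per_status": {s.value: int(n) for s, n in self.n_per_status.items()},
            "marker_distributions": {
                f"{status.value}:{marker}": {
                    "values": [int(v) for v in values],
                    "probs": [float(p) for p in probs],
                }
                for (status, marker), (values, probs) in self.marker_distributions.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if destination is not None:
            if hasattr(destination, "write"):
                destination.write(text)
            else:
                Path(destination).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "SyntheticConfig":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            payload = json.loads(Path(source).read_text(encoding="utf-8"))
        return cls(
            n_per_status={
                Cdkn2aStatus(k): int(v) for k, v in payload["n_per_status"].items()
            },
            marker_distributions={
                (Cdkn2aStatus(key.split(":")[0]), key.split(":")[1]): (
                    tuple(int(v) for v in dist["values"]),
                    tuple(float(p) for p in dist["probs"]),
                )
                for key, dist in payload["marker_distributions"].items()
            },
            seed=int(payload["seed"]),
        )


def empirical_config(cohort: Cohort, seed: int = 0) -> SyntheticConfig:
    """Empirical per-genotype, per-marker distributions of an observed cohort.

    A genotype absent from the cohort is simply omitted from the maps (its
    requested count is then zero and no distribution is needed).
    """
    if len(cohort) == 0:
        raise ValueError("cannot build an empirical config from an empty cohort")
    n_per_status: dict[Cdkn2aStatus, int] = {}
    distributions: dict[tuple[Cdkn2aStatus, str], Categorical] = {}
    for status in Cdkn2aStatus:
        records = [r for r in cohort if r.cdkn2a is status]
        if not records:
            continue
        n_per_status[status] = len(records)
        for marker in MARKERS:
            observed = np.asarray([getattr(r, f"{marker}_pct") for r in records])
            values, counts = np.unique(observed, return_counts=True)
            distributions[(status, marker)] = (
                tuple(int(v) for v in values),
                tuple(float(c) / len(records) for c in counts),
            )
    return SyntheticConfig(
        n_per_status=n_per_status, marker_distributions=distributions, seed=seed
    )


def generate(config: SyntheticConfig, name: str = "synthetic") -> Cohort:
    """Draw a cohort from a config; deterministic given the config's seed."""
    root = np.random.SeedSequence(config.seed)
    children = dict(zip(Cdkn2aStatus, root.spawn(len(Cdkn2aStatus))))
    records: list[PatientRecord] = []
    for status in Cdkn2aStatus:  # fixed order keeps streams stable
        count = int(config.n_per_status.get(status, 0))
        if count == 0:
            continue
        rng = np.random.default_rng(children[status])
        draws = {}
        for marker in MARKERS:
            values, probs = config.marker_distributions[(status, marker)]
            draws[marker] = rng.choice(np.asarray(values), size=count, p=probs)
        for i in range(count):
            records.append(
                PatientRecord(
                    patient_id=f"SYN-{status.value[:3].upper()}-{i:05d}",
                    p16_pct=int(draws["p16"][i]),
                    cd8_pct=int(draws["cd8"][i]),
                    ki67_pct=int(draws["ki67"][i]),
                    cdkn2a=status,
                    split=Split.UNASSIGNED,
                )
            )
    return Cohort(tuple(records), name=name)


def split_cohort(cohort: Cohort, fraction_test: float, seed: int = 0) -> Cohort:
    """Assign test/validation labels, stratified by the wt/mut dichotomy.

    Each stratum is shuffled deterministically and its first
    ``round(fraction_test * n)`` records become the test set, so at fraction
    0.5 the two parts differ by at most one record per stratum.  A stratum
    with fewer than two records cannot be divided and is assigned entirely
    to the test set, with a warning.
    """
    if not 0.0 < fraction_test < 1.0:
        raise ValueError("fraction_test must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    assignment: dict[str, Split] = {}
    for is_mut in (False, True):
        stratum = [r for r in cohort if r.cdkn2a.is_mutated == is_mut]
        if not stratum:
            continue
        if len(stratum) < 2:
            warnings.warn(
                "stratum with fewer than 2 records assigned entirely to the "
                "test set",
                stacklevel=2,
            )
            for r in stratum:
                assignment[r.patient_id] = Split.TEST
            continue
        order = rng.permutation(len(stratum))
        n_test = int(round(fraction_test * len(stratum)))
        test_ids = {stratum[i].patient_id for i in order[:n_test]}
        for r in stratum:
            assignment[r.patient_id] = (
                Split.TEST if r.patient_id in test_ids else Split.VALIDATION
            )
    records = tuple(
        PatientRecord(
            patient_id=r.patient_id,
            p16_pct=r.p16_pct,
            cd8_pct=r.cd8_pct,
            ki67_pct=r.ki67_pct,
            cdkn2a=r.cdkn2a,
            split=assignment[r.patient_id],
        )
        for r in cohort
    )
    return Cohort(records, name=cohort.name)
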