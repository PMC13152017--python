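"""Exclusion accounting, stratified lock-box splitting, frozen manifests.

Splits are subject-wise, never record-wise: a subject id appears in exactly
one of Train/Val/Test. The Test split is the lock box — downstream
evaluation refuses to read it unless explicitly unlocked, and the manifest
hash makes post-hoc membership edits detectable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from .keypoint_io import POSITIVE_LABEL

SPLIT_NAMES = ("train", "val", "test")
MANIFEST_SCHEMA_VERSION = "1.0"


class CohortError(ValueError):
    pass


class ManifestTamperError(RuntimeError):
    """The manifest on disk does not match its recorded hash."""


@dataclass
class ExclusionReport:
    n_enrolled: int
    n_medical_excluded: int
    n_atypical_excluded: int
    n_eligible: int
    eligible_ids: list

    def stages(self) -> list:
        return [
            ("enrolled", self.n_enrolled),
            ("after medical exclusions", self.n_enrolled - self.n_medical_excluded),
            ("after atypical-FM exclusions", self.n_eligible),
        ]


@dataclass
class SplitManifest:
    splits: dict  # name -> sorted id list
    fractions: tuple
    prevalence: dict  # name -> positive fraction
    strata_summary: dict
    seed: int
    schema_version: str = MANIFEST_SCHEMA_VERSION
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    sha256: str = ""

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d.pop("sha256")
        # the timestamp is provenance, not content: two runs with identical
        # inputs must hash identically
        d.pop("timestamp")
        d["splits"] = {k: sorted(v) for k, v in d["splits"].items()}
        d["fractions"] = list(d["fractions"])
        return d

    def compute_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def all_ids(self) -> set:
        return set().union(*self.splits.values())


def apply_exclusions(ids, medical_excluded=(), atypical=()):
    """Remove medically excluded and atypical-FM subjects; account for each stage.

    ``medical_excluded`` and ``atypical`` may overlap; medical exclusion is
    applied first, matching the enrollment flow.
    """
    ids = [str(i) for i in ids]
    id_set = set(ids)
    if len(id_set) != len(ids):
        raise CohortError("duplicate subject ids in cohort")
    for name, flags in (("medical_excluded", medical_excluded), ("atypical", atypical)):
        unknown = set(map(str, flags)) - id_set
        if unknown:
            raise CohortError(f"{name} flags reference unknown ids: {sorted(unknown)[:5]}")
    medical = set(map(str, medical_excluded))
    atyp = set(map(str, atypical)) - medical
    eligible = [i for i in ids if i not in medical and i not in atyp]
    return eligible, ExclusionReport(
        n_enrolled=len(ids),
        n_medical_excluded=len(medical),
        n_atypical_excluded=len(atyp),
        n_eligible=len(eligible),
        eligible_ids=eligible,
    )


def _largest_remainder(n: int, fractions) -> list:
    """Integer allocation of n items to len(fractions) bins, totals exact."""
    quotas = np.asarray(fractions, dtype=float) * n
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    # hand leftover items to the largest fractional remainders (stable ties)
    order = np.argsort(-(quotas - base), kind="stable")
    for k in order[:short]:
        base[k] += 1
    return base.tolist()


def stratified_split(ids, labels, strata=None,
                     fractions=(0.70, 0.10, 0.20), seed: int = 0) -> SplitManifest:
    """Subject-wise stratified Train/Val/Test split.

    Stratification cells are (label, sex) when sex is available, else label
    only. Within each cell, members are shuffled with the seeded generator
    and allocated to the three splits by largest-remainder rounding.
    """
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate subject ids")
    if abs(sum(fractions) - 1.0) > 1e-9 or len(fractions) != 3:
        raise CohortError("fractions must be 3 values summing to 1")
    labels = {str(i): l for i, l in zip(ids, labels)} if not isinstance(labels, dict) else {
        str(k): v for k, v in labels.items()
    }
    strata = strata or {}

    def cell_key(i):
        sex = strata.get(i, {}).get("sex") if isinstance(strata.get(i, {}), dict) else None
        return (labels[i], sex)

    cells: dict[tuple, list] = {}
    for i in ids:
        cells.setdefault(cell_key(i), []).append(i)

    # cells too small to land one member per nonzero fraction fall back to
    # label-only stratification
    min_needed = sum(1 for f in fractions if f > 0)
    if any(len(members) < min_needed for members in cells.values()) and any(
        k[1] is not None for k in cells
    ):
        warnings.warn(
            "stratum too small for allocation; falling back to label-only "
            "stratification",
            stacklevel=2,
        )
        cells = {}
        for i in ids:
            cells.setdefault((labels[i], None), []).append(i)

    rng = np.random.default_rng(seed)
    assignment: dict[str, list] = {name: [] for name in SPLIT_NAMES}
    for key in sorted(cells, key=str):
        members = sorted(cells[key])
        rng.shuffle(members)
        counts = _largest_remainder(len(members), fractions)
        pos = 0
        for split_name, c in zip(SPLIT_NAMES, counts):
            assignment[split_name].extend(members[pos:pos + c])
            pos += c

    prevalence = {}
    strata_summary = {}
    for name in SPLIT_NAMES:
        members = assignment[name]
        n = len(members)
        n_pos = sum(1 for i in members if labels[i] == POSITIVE_LABEL)
        prevalence[name] = n_pos / n if n else 0.0
        sexes: dict[str, int] = {}
        for i in members:
            s = strata.get(i, {}).get("sex") if isinstance(strata.get(i, {}), dict) else None
            sexes[str(s)] = sexes.get(str(s), 0) + 1
        strata_summary[name] = {"n": n, "n_positive": n_pos, "sex_counts": sexes}

    manifest = SplitManifest(
        splits={name: sorted(assignment[name]) for name in SPLIT_NAMES},
        fractions=tuple(fractions),
        prevalence=prevalence,
        strata_summary=strata_summary,
        seed=seed,
    )
    manifest.sha256 = manifest.compute_hash()
    return manifest


def freeze_manifest(manifest: SplitManifest, path) -> str:
    """Write the manifest as canonical JSON with its SHA-256; returns the hash."""
    manifest.sha256 = manifest.compute_hash()
    doc = manifest.canonical_dict()
    doc["timestamp"] = manifest.timestamp
    doc["sha256"] = manifest.sha256
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))
    return manifest.sha256


def load_manifest(path, verify: bool = True) -> SplitManifest:
    """Load a frozen manifest; by default refuse one whose hash fails."""
    doc = json.loads(Path(path).read_text())
    manifest = SplitManifest(
        splits=doc["splits"],
        fractions=tuple(doc["fractions"]),
        prevalence=doc["prevalence"],
        strata_summary=doc["strata_summary"],
        seed=doc["seed"],
        schema_version=doc.get("schema_version", MANIFEST_SCHEMA_VERSION),
        timestamp=doc["timestamp"],
        sha256=doc.get("sha256", ""),
    )
    if verify:
        expected = manifest.compute_hash()
        if manifest.sha256 != expected:
            raise ManifestTamperError(
                f"manifest hash mismatch: recorded {manifest.sha256[:12]}..., "
                f"recomputed {expected[:12]}... — refusing to evaluate"
            )
    return manifest


def verify_manifest(path) -> bool:
    """True iff the manifest at ``path`` matches its recorded hash."""
    try:
        load_manifest(path, verify=True)
    except ManifestTamperError:
        return False
    return True
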