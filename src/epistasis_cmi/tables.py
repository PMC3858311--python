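"""Stratified two-locus genotype count tables.

The universal input of every interaction test in this package is a pair of
genotype count matrices, one for cases and one for controls, over the same
grid of genotype classes at two diallelic loci G and H.  Genotype classes are
labelled by risk-allele count (0, 1 or 2); a locus with only two observed
classes (e.g. a marker where the variant homozygote is absent) is kept at its
observed dimension rather than padded with empty rows.

Bundled with the data model are the published count tables used as worked
examples: the Kilifi malaria birth-cohort tables (hemoglobin AS x
alpha(+)-thalassemia, hospital-admission and severe-malaria phenotypes) and
four cancer case-control tables for the MDM2 SNP309 x p53 codon-72 pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableValidationError",
    "StratifiedGenotypeTable",
    "table_from_counts",
    "read_individual_csv",
    "write_individual_csv",
    "read_count_json",
    "write_count_json",
    "fixture_table",
    "FIXTURE_NAMES",
]

CONTROL, CASE = 0, 1


class TableValidationError(ValueError):
    """Raised when genotype counts or levels violate the table contract."""


def _check_levels(levels, name):
    levels = tuple(int(v) for v in levels)
    if len(levels) < 2:
        raise TableValidationError(f"{name}: need at least 2 genotype levels, got {levels}")
    if len(set(levels)) != len(levels):
        raise TableValidationError(f"{name}: duplicate levels {levels}")
    if any(v not in (0, 1, 2) for v in levels):
        raise TableValidationError(f"{name}: levels must be risk-allele counts in {{0,1,2}}, got {levels}")
    if list(levels) != sorted(levels):
        raise TableValidationError(f"{name}: levels must be ascending, got {levels}")
    return levels


@dataclass(frozen=True)
class StratifiedGenotypeTable:
    """Case/control genotype counts for a pair of loci.

    ``counts`` has shape ``(2, r, c)`` with stratum index 0 = control,
    1 = case; rows index genotype classes at locus G (``levels_g``) and
    columns at locus H (``levels_h``), both as ascending risk-allele counts.
    """

    counts: np.ndarray
    levels_g: tuple = (0, 1, 2)
    levels_h: tuple = (0, 1, 2)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 3 or counts.shape[0] != 2:
            raise TableValidationError(f"counts: expected shape (2, r, c), got {counts.shape}")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise TableValidationError("counts: non-integer entry")
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise TableValidationError("counts: negative entry")
        lg = _check_levels(self.levels_g, "levels_g")
        lh = _check_levels(self.levels_h, "levels_h")
        if counts.shape[1] != len(lg) or counts.shape[2] != len(lh):
            raise TableValidationError(
                f"counts: shape {counts.shape[1:]} does not match levels "
                f"({len(lg)} x {len(lh)})"
            )
        for d, nm in ((CONTROL, "control"), (CASE, "case")):
            if counts[d].sum() == 0:
                raise TableValidationError(f"empty stratum: {nm}")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "levels_g", lg)
        object.__setattr__(self, "levels_h", lh)

    # -- basic accessors -------------------------------------------------
    @property
    def case_counts(self) -> np.ndarray:
        return self.counts[CASE]

    @property
    def control_counts(self) -> np.ndarray:
        return self.counts[CONTROL]

    @property
    def n_case(self) -> int:
        return int(self.counts[CASE].sum())

    @property
    def n_control(self) -> int:
        return int(self.counts[CONTROL].sum())

    @property
    def n(self) -> int:
        """Total number of individuals N."""
        return int(self.counts.sum())

    @property
    def case_fraction(self) -> float:
        """P_A, the sampled case proportion N_case / N."""
        return self.n_case / self.n

    @property
    def shape(self):
        """(r, c): genotype-class dimensions."""
        return self.counts.shape[1:]

    # -- simple transforms ----------------------------------------------
    def swap_loci(self) -> "StratifiedGenotypeTable":
        """Exchange the roles of the two loci (transpose both strata)."""
        return StratifiedGenotypeTable(
            np.transpose(self.counts, (0, 2, 1)).copy(), self.levels_h, self.levels_g
        )

    def scaled(self, k: int) -> "StratifiedGenotypeTable":
        """Multiply every cell count by a positive integer ``k``."""
        if int(k) != k or k < 1:
            raise TableValidationError("scale factor must be a positive integer")
        return StratifiedGenotypeTable(self.counts * int(k), self.levels_g, self.levels_h)

    def to_individual_frame(self) -> pd.DataFrame:
        """Expand to one row per counted individual (sample_id, g, h, status)."""
        rows = []
        i = 0
        for d in (CONTROL, CASE):
            for a, g in enumerate(self.levels_g):
                for b, h in enumerate(self.levels_h):
                    for _ in range(int(self.counts[d, a, b])):
                        rows.append((f"s{i}", g, h, d))
                        i += 1
        return pd.DataFrame(rows, columns=["sample_id", "g", "h", "status"])


def table_from_counts(case_counts, control_counts, levels_g=None, levels_h=None) -> StratifiedGenotypeTable:
    """Build a validated table from separate case and control matrices.

    Levels default to ``0..r-1`` / ``0..c-1`` when not given.
    """
    case = np.asarray(case_counts)
    ctrl = np.asarray(control_counts)
    if case.shape != ctrl.shape:
        raise TableValidationError(
            f"case_counts shape {case.shape} != control_counts shape {ctrl.shape}"
        )
    if case.ndim != 2:
        raise TableValidationError("count matrices must be 2-dimensional")
    if levels_g is None:
        levels_g = tuple(range(case.shape[0]))
    if levels_h is None:
        levels_h = tuple(range(case.shape[1]))
    return StratifiedGenotypeTable(np.stack([ctrl, case]), tuple(levels_g), tuple(levels_h))


# ---------------------------------------------------------------------------
# per-individual CSV interchange
# ---------------------------------------------------------------------------

def read_individual_csv(path, full_levels: bool = False) -> StratifiedGenotypeTable:
    """Aggregate a per-individual CSV (sample_id,g,h,status) into a table.

    Genotype levels are the sorted distinct observed values unless
    ``full_levels`` forces the complete {0,1,2} grid at both loci.
    Duplicate sample ids trigger a warning, not an error.
    """
    df = pd.read_csv(path)
    required = ["sample_id", "g", "h", "status"]
    if list(df.columns[:4]) != required:
        raise TableValidationError(f"{path}: header must be {','.join(required)}")
    for col in ("g", "h", "status"):
        vals = df[col]
        bad = ~vals.isin((0, 1, 2) if col != "status" else (0, 1))
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise TableValidationError(f"{path}: line {line}: out-of-range {col}={vals[bad.idxmax()]}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
        warnings.warn(f"duplicated sample_id(s): {', '.join(map(str, dups[:5]))}")
    levels_g = (0, 1, 2) if full_levels else tuple(sorted(df["g"].unique()))
    levels_h = (0, 1, 2) if full_levels else tuple(sorted(df["h"].unique()))
    counts = np.zeros((2, len(levels_g), len(levels_h)), dtype=np.int64)
    gi = {v: i for i, v in enumerate(levels_g)}
    hi = {v: i for i, v in enumerate(levels_h)}
    for _, row in df.iterrows():
        counts[int(row["status"]), gi[int(row["g"])], hi[int(row["h"])]] += 1
    return StratifiedGenotypeTable(counts, levels_g, levels_h)


def write_individual_csv(table: StratifiedGenotypeTable, path) -> None:
    table.to_individual_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# count-table JSON interchange
# ---------------------------------------------------------------------------

def write_count_json(table: StratifiedGenotypeTable, path) -> None:
    """Write the labelled case/control matrices as JSON."""
    payload = {
        "levels_g": list(table.levels_g),
        "levels_h": list(table.levels_h),
        "case": table.case_counts.tolist(),
        "control": table.control_counts.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_count_json(path) -> StratifiedGenotypeTable:
    payload = json.loads(Path(path).read_text())
    for key in ("case", "control", "levels_g", "levels_h"):
        if key not in payload:
            raise TableValidationError(f"{path}: missing key '{key}'")
    return table_from_counts(
        payload["case"], payload["control"], payload["levels_g"], payload["levels_h"]
    )


# ---------------------------------------------------------------------------
# published worked-example tables
# ---------------------------------------------------------------------------
# Malaria tables: rows are Hb genotype (HbAA=0, HbAS=1; the protective S
# variant is scored as the "risk" allele), columns are alpha(+)-thalassemia
# -alpha allele count (aa/aa=0, -a/aa=1, -a/-a=2).  The severe-malaria table
# retains its zero-case cell (HbAS, aa/aa).
# Cancer tables: rows are p53 codon 72 (Arg/Arg=0, Arg/Pro=1, Pro/Pro=2),
# columns MDM2 SNP309 (TT=0, TG=1, GG=2); Pro and G are the variant alleles.
_FIXTURES = {
    "malaria_admission": dict(
        case=[[168, 187, 56], [6, 9, 10]],
        control=[[458, 680, 246], [107, 141, 36]],
        levels_g=(0, 1), levels_h=(0, 1, 2),
    ),
    "severe_malaria": dict(
        case=[[67, 53, 17], [0, 2, 5]],
        control=[[559, 814, 285], [113, 148, 41]],
        levels_g=(0, 1), levels_h=(0, 1, 2),
    ),
    "gcc": dict(  # gastric cardia cancer
        case=[[19, 59, 45], [61, 119, 65], [27, 72, 33]],
        control=[[96, 162, 58], [150, 222, 114], [52, 114, 32]],
    ),
    "lc": dict(  # lung cancer
        case=[[62, 170, 89], [127, 259, 120], [60, 132, 87]],
        control=[[122, 223, 80], [222, 343, 166], [74, 145, 45]],
    ),
    "hcc": dict(  # hepatocellular carcinoma
        case=[[23, 48, 39], [18, 58, 35], [4, 19, 43]],
        control=[[40, 56, 28], [38, 53, 45], [6, 23, 8]],
    ),
    "bc": dict(  # breast cancer
        case=[[349, 317, 104], [218, 266, 63], [40, 45, 14]],
        control=[[488, 539, 166], [346, 365, 92], [60, 52, 10]],
    ),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture_table(name: str) -> StratifiedGenotypeTable:
    """Return one of the packaged published count tables by short name."""
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
    return table_from_counts(
        spec["case"], spec["control"],
        spec.get("levels_g", (0, 1, 2)), spec.get("levels_h", (0, 1, 2)),
    )
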