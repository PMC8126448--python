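"""Reading, validation and writing of metabolite intensity datasets.

The central container is :class:`IntensityTensor`, the metabolite x
individual x condition array of natural-scale intensities for a complete
paired two-condition design. Intensities are stored on the natural scale;
the log2 transform is applied exactly once, downstream, by the analysis
stages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DesignError, FormatError

#: Canonical condition labels, in analysis order (baseline first).
CONDITIONS: tuple[str, str] = ("post-absorptive", "fasted")

_CONDITION_ALIASES = {
    "post-absorptive": "post-absorptive",
    "postabsorptive": "post-absorptive",
    "post_absorptive": "post-absorptive",
    "post": "post-absorptive",
    "baseline": "post-absorptive",
    "fasted": "fasted",
    "fasting": "fasted",
    "fast": "fasted",
}


def normalize_condition(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _CONDITION_ALIASES:
        raise FormatError(
            f"unknown condition label {label!r}; expected one of {sorted(set(_CONDITION_ALIASES))}"
        )
    return _CONDITION_ALIASES[key]


@dataclass
class IntensityTensor:
    """Complete paired intensity data with metadata.

    Attributes
    ----------
    values
        Array of shape (n_metabolites, n_individuals, 2), natural-scale
        intensities, finite and >= 0. The condition axis is ordered as
        :data:`CONDITIONS` (post-absorptive, fasted).
    metabolite_ids, individual_ids
        Unique string labels for the first two axes.
    annotations
        Optional per-metabolite table indexed by metabolite ID with columns
        ``identified`` (bool) and ``super_pathway`` (str).
    """

    values: np.ndarray
    metabolite_ids: list[str]
    individual_ids: list[str]
    conditions: tuple[str, str] = CONDITIONS
    annotations: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.validate()

    def validate(self) -> None:
        g, i = len(self.metabolite_ids), len(self.individual_ids)
        if self.values.shape != (g, i, 2):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"({g} metabolites, {i} individuals, 2 conditions)"
            )
        if tuple(self.conditions) != CONDITIONS:
            raise FormatError(f"conditions must be {CONDITIONS}, got {self.conditions}")
        if len(set(self.metabolite_ids)) != g:
            raise FormatError("duplicate metabolite IDs")
        if len(set(self.individual_ids)) != i:
            raise FormatError("duplicate individual IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities contain non-finite values")
        if np.any(self.values < 0):
            raise ValueError("intensities contain negative values")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def condition_index(self, condition: str) -> int:
        return self.conditions.index(normalize_condition(condition))

    def condition_slice(self, condition: str) -> pd.DataFrame:
        """Natural-scale metabolite x individual matrix for one condition."""
        return pd.DataFrame(
            self.values[:, :, self.condition_index(condition)],
            index=self.metabolite_ids,
            columns=self.individual_ids,
        )

    def log2_values(self) -> np.ndarray:
        """log2 of the tensor; raises on zero intensities, naming the offender."""
        zero = np.argwhere(self.values == 0)
        if zero.size:
            g, i, c = zero[0]
            raise ValueError(
                f"zero intensity for metabolite {self.metabolite_ids[g]!r}, sample "
                f"{self.individual_ids[i]}_{self.conditions[c]}: log2 undefined"
            )
        return np.log2(self.values)

    def sample_ids(self) -> list[str]:
        """Sample labels ``<subject>_<condition>``, condition-major (all post first)."""
        return [f"{ind}_{cond}" for cond in self.conditions for ind in self.individual_ids]

    def to_matrix(self) -> pd.DataFrame:
        """Metabolite x sample natural-scale matrix (column order = sample_ids)."""
        mat = np.concatenate([self.values[:, :, 0], self.values[:, :, 1]], axis=1)
        return pd.DataFrame(mat, index=self.metabolite_ids, columns=self.sample_ids())


def median_scale(tensor: IntensityTensor) -> IntensityTensor:
    """Per-sample median scaling: divide each sample column by its median, then
    multiply by the grand median so the overall scale is preserved. OFF by
    default in the pipeline."""
    vals = tensor.values.copy()
    med = np.median(vals, axis=0, keepdims=True)  # (1, I, 2)
    if np.any(med <= 0):
        raise ValueError("non-positive sample median; cannot median-scale")
    vals = vals / med * np.median(vals)
    return IntensityTensor(
        vals, tensor.metabolite_ids, tensor.individual_ids, tensor.conditions, tensor.annotations
    )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")


def load_dataset(
    intensity_path: str | Path,
    sample_sheet_path: str | Path,
    annotation_path: str | Path | None = None,
) -> IntensityTensor:
    """Assemble the 3D tensor from an intensity matrix and a sample sheet.

    The intensity table has metabolites as rows (first column = metabolite ID)
    and samples as columns. The sample sheet maps ``sample_id`` to
    ``subject_id`` and ``condition``. Samples absent from the sheet are
    rejected; each subject must have exactly one sample per condition.
    """
    intens = _read_table(intensity_path)
    sheet = _read_table(sample_sheet_path)

    required = {"sample_id", "subject_id", "condition"}
    if not required.issubset(sheet.columns):
        raise FormatError(f"sample sheet must have columns {sorted(required)}")

    metab_col = intens.columns[0]
    metabolites = intens[metab_col].astype(str).tolist()
    if len(set(metabolites)) != len(metabolites):
        dupes = sorted({m for m in metabolites if metabolites.count(m) > 1})
        raise FormatError(f"duplicate metabolite IDs: {dupes[:5]}")
    mat = intens.set_index(metab_col)

    sheet = sheet.assign(condition=sheet["condition"].map(normalize_condition))
    known = set(sheet["sample_id"].astype(str))
    unknown = [c for c in mat.columns if c not in known]
    if unknown:
        raise FormatError(f"intensity columns not in sample sheet: {unknown}")

    # sample lookup and pairing check
    lookup: dict[tuple[str, str], str] = {}
    for row in sheet.itertuples(index=False):
        key = (str(row.subject_id), row.condition)
        if key in lookup:
            raise DesignError(f"subject {row.subject_id} has duplicate {row.condition} samples")
        lookup[key] = str(row.sample_id)
    subjects = list(dict.fromkeys(str(s) for s in sheet["subject_id"]))
    for subj in subjects:
        for cond in CONDITIONS:
            if (subj, cond) not in lookup:
                raise DesignError(f"subject {subj} is missing its {cond} sample: design is unpaired")
    missing_cols = [s for s in lookup.values() if s not in mat.columns]
    if missing_cols:
        raise FormatError(f"sample sheet samples absent from intensity table: {missing_cols}")

    vals = np.empty((len(metabolites), len(subjects), 2), dtype=float)
    for ci, cond in enumerate(CONDITIONS):
        cols = [lookup[(subj, cond)] for subj in subjects]
        vals[:, :, ci] = mat[cols].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("negative intensity values in input table")

    annotations = None
    if annotation_path is not None:
        ann = _read_table(annotation_path)
        ann_id = ann.columns[0]
        annotations = ann.set_index(ann_id)
        annotations.index = annotations.index.astype(str)
        if "identified" in annotations.columns:
            annotations["identified"] = annotations["identified"].astype(bool)

    return IntensityTensor(vals, metabolites, subjects, CONDITIONS, annotations)


def write_dataset(tensor: IntensityTensor, out_dir: str | Path) -> dict[str, Path]:
    """Write intensity matrix, sample sheet and annotations as TSV.

    Returns the mapping of logical names to written paths. The written files
    round-trip through :func:`load_dataset` losslessly (``float`` repr).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / "intensities.tsv",
        "samples": out / "samples.tsv",
    }
    mat = tensor.to_matrix()
    mat.index.name = "metabolite_id"
    mat.to_csv(paths["intensities"], sep="\t", float_format="%.17g")

    rows = [
        {"sample_id": f"{ind}_{cond}", "subject_id": ind, "condition": cond}
        for cond in tensor.conditions
        for ind in tensor.individual_ids
    ]
    pd.DataFrame(rows).to_csv(paths["samples"], sep="\t", index=False)

    if tensor.annotations is not None:
        paths["annotations"] = out / "annotations.tsv"
        ann = tensor.annotations.copy()
        ann.index.name = "metabolite_id"
        ann.to_csv(paths["annotations"], sep="\t")
    return paths


def summarize_catalogue(tensor: IntensityTensor) -> dict[str, int]:
    """Counts of total / identified / unidentified metabolites.

    Metabolites without an annotation row (or with no annotation table at
    all) count as unidentified, with a warning.
    """
    total = tensor.n_metabolites
    if tensor.annotations is None or "identified" not in tensor.annotations.columns:
        warnings.warn("no metabolite annotations: counting all metabolites as unidentified")
        identified = 0
    else:
        ann = tensor.annotations["identified"]
        covered = [m for m in tensor.metabolite_ids if m in ann.index]
        if len(covered) < total:
            warnings.warn(
                f"{total - len(covered)} metabolites lack annotations; counted as unidentified"
            )
        identified = int(ann.loc[covered].sum())
    return {"total": total, "identified": identified, "unidentified": total - identified}
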