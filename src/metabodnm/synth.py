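"""Synthetic paired two-condition metabolome generator with planted ground truth.

The generator emulates the study design the pipeline targets: a plasma
metabolome of ~322 metabolites measured in 8 individuals in a paired
post-absorptive / 24-h-fasted design. Log2 intensities are Gaussian:

    y[g,i,c] = mu + b[i] + lfc[g]*1{c=fasted}
               + sd_eff * ( sqrt(rho_eff) * f[m(g),i,c] + sqrt(1-rho_eff) * e[g,i,c] )

with a subject random effect ``b`` shared across conditions (this is what
makes the design paired), a per-module latent factor ``f`` inducing a
within-module correlation of ``rho_eff`` (the sqrt-loading construction is
positive semidefinite for any rho in [0,1)), a planted log2 fold change
applied to the fasted slice, and i.i.d. residuals. A designated dynamic
network marker (DNM) module is perturbed *only in the fasted slice*: its
noise sd is multiplied by ``dnm_cv_multiplier`` and its within-module
correlation is raised to ``dnm_within_module_correlation_fasted``, giving the
elevated between-individual variation and co-variation the DNM procedure
looks for. Output intensities are 2**y, hence strictly positive.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .dataio import CONDITIONS, IntensityTensor, write_dataset
from .exceptions import AlignmentError, ConfigurationError

_SUPER_PATHWAYS = (
    "Amino Acid",
    "Lipid",
    "Carbohydrate",
    "Nucleotide",
    "Peptide",
    "Energy",
    "Cofactors and Vitamins",
    "Xenobiotics",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic paired metabolome.

    Defaults mirror the target study's dimensions (322 metabolites, 8
    individuals, two conditions) and its reported effect scale (log2 fold
    changes up to +/-2.5). ``n_modules`` defaults to 14 so the planted DNM
    module carries the label 14; the count itself is cosmetic.
    """

    n_metabolites: int = 322
    n_individuals: int = 8
    n_modules: int = 14
    dnm_module_size: int = 23
    base_within_module_correlation: float = 0.3
    dnm_within_module_correlation_fasted: float = 0.9
    subject_effect_sd: float = 0.5
    residual_sd: float = 0.4
    dnm_cv_multiplier: float = 3.0
    lfc_increase_fraction: float = 0.25
    lfc_decrease_fraction: float = 0.22
    lfc_magnitude_range: tuple[float, float] = (0.5, 2.5)
    mean_log2_intensity: float = 10.0
    identified_fraction: float = 219 / 322
    plant_dnm: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites < 1 or self.n_individuals < 2 or self.n_modules < 1:
            raise ConfigurationError("need >=1 metabolite, >=2 individuals, >=1 module")
        for name in ("base_within_module_correlation", "dnm_within_module_correlation_fasted"):
            rho = getattr(self, name)
            if not 0.0 <= rho < 1.0:
                raise ConfigurationError(f"{name}={rho} outside [0, 1): covariance not PSD")
        if self.lfc_increase_fraction < 0 or self.lfc_decrease_fraction < 0:
            raise ConfigurationError("LFC fractions must be >= 0")
        if self.lfc_increase_fraction + self.lfc_decrease_fraction > 1.0:
            raise ConfigurationError("LFC fractions sum to more than 1")
        if self.dnm_cv_multiplier < 1.0:
            raise ConfigurationError("dnm_cv_multiplier must be >= 1")
        lo, hi = self.lfc_magnitude_range
        if not 0 <= lo <= hi:
            raise ConfigurationError("lfc_magnitude_range must satisfy 0 <= low <= high")
        if self.subject_effect_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        self.module_sizes()  # raises if sizes cannot partition n_metabolites

    def module_sizes(self) -> list[int]:
        """Module sizes in label order 1..n_modules; the last module is the
        (candidate) DNM module with exactly ``dnm_module_size`` members."""
        if self.n_modules == 1:
            return [self.n_metabolites]
        rest = self.n_metabolites - self.dnm_module_size
        k = self.n_modules - 1
        if self.dnm_module_size < 1 or rest < k:
            raise ConfigurationError(
                f"cannot partition {self.n_metabolites} metabolites into {self.n_modules} "
                f"non-empty modules with a DNM module of {self.dnm_module_size}"
            )
        base, extra = divmod(rest, k)
        sizes = [base + (1 if j < extra else 0) for j in range(k)]
        return sizes + [self.dnm_module_size]


@dataclass
class PlantedTruth:
    """Ground truth planted by the generator, for downstream recovery checks."""

    module_assignment: pd.Series  # metabolite -> int module label (1-based)
    dnm_module: int | None
    de_class: pd.Series  # metabolite -> {"increase", "decrease", "no_change"}
    true_lfc: pd.Series  # metabolite -> log2 units

    def dnm_members(self) -> set[str]:
        if self.dnm_module is None:
            return set()
        return set(self.module_assignment.index[self.module_assignment == self.dnm_module])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "module": self.module_assignment,
                "de_class": self.de_class,
                "true_lfc": self.true_lfc,
            }
        )
        df["is_dnm_module"] = (
            self.module_assignment == self.dnm_module if self.dnm_module is not None else False
        )
        df.index.name = "metabolite_id"
        return df


def generate_paired_metabolome(config: SynthConfig) -> tuple[IntensityTensor, PlantedTruth]:
    """Draw one synthetic dataset; same config (incl. seed) => bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    g, n, k = config.n_metabolites, config.n_individuals, config.n_modules

    width = len(str(g))
    metabolites = [f"M{j + 1:0{width}d}" for j in range(g)]
    individuals = [f"D{j + 1}" for j in range(n)]

    sizes = config.module_sizes()
    module = np.repeat(np.arange(1, k + 1), sizes)
    dnm_label: int | None = k if (config.plant_dnm and k >= 1) else None

    # planted differential expression
    de_class = np.array(["no_change"] * g, dtype=object)
    n_inc = int(round(config.lfc_increase_fraction * g))
    n_dec = int(round(config.lfc_decrease_fraction * g))
    picks = rng.permutation(g)[: n_inc + n_dec]
    de_class[picks[:n_inc]] = "increase"
    de_class[picks[n_inc:]] = "decrease"
    lo, hi = config.lfc_magnitude_range
    magnitude = rng.uniform(lo, hi, size=g)
    true_lfc = np.where(
        de_class == "increase", magnitude, np.where(de_class == "decrease", -magnitude, 0.0)
    )

    subject = rng.normal(0.0, config.subject_effect_sd, size=n)
    factors = rng.normal(size=(k, n, 2))  # per-module latent factor, per individual x condition
    resid = rng.normal(size=(g, n, 2))

    rho = np.full((g, 2), config.base_within_module_correlation)
    sd = np.full((g, 2), config.residual_sd)
    if dnm_label is not None:
        in_dnm = module == dnm_label
        rho[in_dnm, 1] = config.dnm_within_module_correlation_fasted
        sd[in_dnm, 1] = config.residual_sd * config.dnm_cv_multiplier

    noise = np.sqrt(rho)[:, None, :] * factors[module - 1] + np.sqrt(1.0 - rho)[:, None, :] * resid
    y = (
        config.mean_log2_intensity
        + subject[None, :, None]
        + sd[:, None, :] * noise
    )
    y[:, :, 1] += true_lfc[:, None]

    n_ident = int(round(config.identified_fraction * g))
    identified = np.zeros(g, dtype=bool)
    identified[rng.permutation(g)[:n_ident]] = True
    annotations = pd.DataFrame(
        {
            "identified": identified,
            "super_pathway": [
                _SUPER_PATHWAYS[j] if ok else "Unknown"
                for j, ok in zip(rng.integers(0, len(_SUPER_PATHWAYS), size=g), identified)
            ],
        },
        index=pd.Index(metabolites, name="metabolite_id"),
    )

    tensor = IntensityTensor(2.0 ** y, metabolites, individuals, CONDITIONS, annotations)
    idx = pd.Index(metabolites, name="metabolite_id")
    truth = PlantedTruth(
        module_assignment=pd.Series(module, index=idx, name="module"),
        dnm_module=dnm_label,
        de_class=pd.Series(de_class, index=idx, name="de_class"),
        true_lfc=pd.Series(true_lfc, index=idx, name="true_lfc"),
    )
    return tensor, truth


def _check_aligned(truth: PlantedTruth, index: pd.Index, what: str) -> None:
    if set(index) != set(truth.module_assignment.index):
        raise AlignmentError(f"{what} metabolite set does not match the planted truth")


def truth_recovery_summary(
    truth: PlantedTruth,
    diffexpr_table: pd.DataFrame | None = None,
    partition_assignment: pd.Series | None = None,
    selected_dnm_members: set[str] | None = None,
) -> dict[str, float | bool | None]:
    """Recovery metrics of downstream results against the planted truth.

    Returns DE sensitivity (recall of planted changes, with direction) and
    false discovery proportion, the adjusted Rand index of a module
    partition, and the DNM hit indicator: the selected module is a hit iff
    its Jaccard overlap with the planted DNM module is maximal among all
    modules of the partition (requires both a partition and a selection).
    """
    out: dict[str, float | bool | None] = {}
    if diffexpr_table is not None:
        _check_aligned(truth, diffexpr_table.index, "differential-expression table")
        called = diffexpr_table["change_class"].reindex(truth.de_class.index)
        truly = truth.de_class != "no_change"
        positives = called != "no_change"
        out["de_sensitivity"] = (
            float((positives & (called == truth.de_class)).sum() / truly.sum())
            if truly.any()
            else float("nan")
        )
        out["de_fdr"] = (
            float((positives & ~truly).sum() / positives.sum()) if positives.any() else 0.0
        )
    if partition_assignment is not None:
        _check_aligned(truth, partition_assignment.index, "partition")
        order = truth.module_assignment.index
        out["module_ari"] = float(
            adjusted_rand_score(
                truth.module_assignment.loc[order], partition_assignment.loc[order]
            )
        )
    if selected_dnm_members is not None:
        planted = truth.dnm_members()
        if not planted:
            out["dnm_hit"] = False
        elif partition_assignment is None:
            out["dnm_hit"] = None
        else:
            best = max(
                _jaccard(set(partition_assignment.index[partition_assignment == lab]), planted)
                for lab in partition_assignment.unique()
            )
            out["dnm_hit"] = bool(
                selected_dnm_members
                and np.isclose(_jaccard(set(selected_dnm_members), planted), best)
            )
    return out


def strong_effect_config(seed: int = 0, **overrides) -> SynthConfig:
    """The documented strong-effect benchmark configuration.

    A 32-metabolite DNM module with fasted within-module correlation 0.998
    and a 4x noise-sd multiplier against a 0.2 background correlation, and
    planted fold changes of at least 1 log2 unit: a pronounced but not
    degenerate critical-transition signature, used for the
    planted-recovery benchmarks.
    """
    params = dict(
        dnm_within_module_correlation_fasted=0.998,
        base_within_module_correlation=0.2,
        dnm_cv_multiplier=4.0,
        dnm_module_size=32,
        lfc_magnitude_range=(1.0, 2.5),
        seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


def null_config(seed: int = 0, **overrides) -> SynthConfig:
    """Null configuration: no differential expression and no DNM perturbation,
    so the two condition slices are exchangeable draws."""
    params = dict(
        lfc_increase_fraction=0.0,
        lfc_decrease_fraction=0.0,
        dnm_cv_multiplier=1.0,
        plant_dnm=False,
        seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def write_synthetic_dataset(
    out_dir: str | Path, config: SynthConfig | None = None
) -> tuple[IntensityTensor, PlantedTruth, dict[str, Path]]:
    """Generate one dataset and write intensities, sample sheet, annotations,
    planted truth and the generating config under ``out_dir``."""
    config = config or SynthConfig()
    tensor, truth = generate_paired_metabolome(config)
    out = Path(out_dir)
    paths = write_dataset(tensor, out)
    paths["truth"] = out / "truth.tsv"
    truth.to_frame().to_csv(paths["truth"], sep="\t")
    paths["config"] = out / "synth_config.json"
    cfg = dataclasses.asdict(config)
    cfg["lfc_magnitude_range"] = list(cfg["lfc_magnitude_range"])
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return tensor, truth, paths
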