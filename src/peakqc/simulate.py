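"""Synthetic multi-run targeted-MS datasets with ground-truth peak quality.

Each peptide elutes as an exponentially-modified-Gaussian (EMG) peak; its
3-5 fragment transitions share the elution profile and differ only in their
relative abundances, and the spiked heavy standard mirrors the light
endogenous traces up to an intensity scale. Peak boundaries are set at
apex +/- 4 sigma, as an analyst would integrate a clean peak.

Quality defects are injected per (run, peptide, fragment) from a
configurable menu modelled on what analysts flag in real chromatograms:

* ``jagged``       -- multiplicative noise (detector noise / low signal);
* ``bimodal``      -- a second partially-resolved mode;
* ``tailing``      -- severe exponential tailing (column overload/damage);
* ``interference`` -- a co-eluting near-isobaric species added to the
  endogenous trace only, distorting shape and transition ratios;
* ``background``   -- constant chemical background across the peak;
* ``rt_shift``     -- apex displacement of one transition (co-elution
  violation);
* ``low_standard`` -- weak spiked-standard signal for a whole peptide.

Ground truth labels a pair ``flag`` as soon as any applied defect reaches
its configured "visible" magnitude threshold; defect-free pairs are ``ok``.
All randomness flows from a single integer seed via numpy SeedSequence, so
identical configs give byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .datamodel import Label, TransitionKey, TransitionTrace
from .errors import InvalidConfig, UnknownDefect
from .io_skyline import (BoundaryTableRow, DialectConfig, write_boundaries,
                         write_chromatograms, write_table)

#: order in which stacked defects are applied to a trace
DEFECT_ORDER = ("tailing", "rt_shift", "bimodal", "interference",
                "background", "jagged", "low_standard")


@dataclass
class DefectConfig:
    """Probability, magnitude and labelling threshold of one defect type."""

    probability: float = 0.0
    magnitude: float = 1.0
    #: magnitude at/above which an analyst would visibly flag the pair
    visible_threshold: float = 1.0

    def validate(self, name: str) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise InvalidConfig(f"{name}: probability must be in [0, 1]")
        if self.magnitude <= 0:
            raise InvalidConfig(f"{name}: magnitude must be > 0")


def default_defects() -> dict[str, DefectConfig]:
    """Defect menu at visibly-flaggable magnitudes.

    Probabilities are set so roughly a third of pairs carry at least one
    defect, matching the flag prevalence seen in annotated MRM training
    sets (about 35-45% flagged).
    """
    return {
        "jagged": DefectConfig(0.07, magnitude=0.15, visible_threshold=0.05),
        "bimodal": DefectConfig(0.06, magnitude=0.5, visible_threshold=0.2),
        "tailing": DefectConfig(0.06, magnitude=4.0, visible_threshold=2.0),
        "interference": DefectConfig(0.07, magnitude=0.6, visible_threshold=0.2),
        "background": DefectConfig(0.06, magnitude=0.15, visible_threshold=0.05),
        "rt_shift": DefectConfig(0.06, magnitude=0.08, visible_threshold=0.03),
        "low_standard": DefectConfig(0.05, magnitude=30.0, visible_threshold=5.0),
    }


@dataclass
class SimulationConfig:
    """Study design and peak-shape parameters for a simulated dataset.

    Defaults mirror a typical scheduled-MRM biomarker panel: 36 peptides x
    4 fragment transitions (144 transitions) in both isotope labels, 8 runs,
    ~1 s cycle time (0.015 min sampling), peaks of sigma 0.06 min with mild
    intrinsic tailing (tau = 0.3 sigma).
    """

    n_runs: int = 8
    n_peptides: int = 36
    fragments_per_peptide: int = 4
    sampling_interval: float = 0.015   # minutes between points
    rt_range: tuple = (10.0, 50.0)     # gradient window for apexes, minutes
    sigma: float = 0.06                # Gaussian width, minutes
    tau_over_sigma: float = 0.3        # intrinsic EMG tail
    endo_scale: float = 1.0e5          # endogenous peak-height scale, counts
    std_scale_factor: float = 3.0      # standards spiked above endogenous
    peptide_scale_sd: float = 0.5      # lognormal spread of peptide abundance
    run_scale_sd: float = 0.10         # lognormal run-to-run intensity factor
    run_rt_jitter: float = 0.005       # per-run apex jitter SD, minutes
    base_noise_cv: float = 0.005       # multiplicative noise on clean peaks
    noise_floor: float = 2.0           # additive noise SD, counts
    defects: dict = field(default_factory=default_defects)
    seed: int = 0

    def validate(self) -> None:
        if self.n_runs < 1 or self.n_peptides < 1:
            raise InvalidConfig("n_runs and n_peptides must be >= 1")
        if not 3 <= self.fragments_per_peptide <= 5:
            raise InvalidConfig("fragments_per_peptide must be in 3..5")
        if self.sigma <= 0 or self.tau_over_sigma <= 0:
            raise InvalidConfig("sigma and tau must be > 0")
        if self.sampling_interval <= 0:
            raise InvalidConfig("sampling_interval must be > 0")
        for name, d in self.defects.items():
            if name not in DEFECT_ORDER:
                raise InvalidConfig(f"unknown defect {name!r}")
            d.validate(name)


def clean_config(**overrides) -> SimulationConfig:
    """A config with every defect probability zeroed (all-ok dataset)."""
    cfg = SimulationConfig(**overrides)
    cfg.defects = {k: replace(v, probability=0.0) for k, v in cfg.defects.items()}
    return cfg


# ---------------------------------------------------------------------------
# peak shape and defect injection
# ---------------------------------------------------------------------------

def _emg_shape(times: np.ndarray, mu: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-height EMG profile on the sampled grid."""
    k = max(tau / sigma, 1e-6)
    y = exponnorm.pdf(times, K=k, loc=mu, scale=sigma)
    peak = y.max()
    return y / peak if peak > 0 else y


def inject_defect(trace: TransitionTrace, defect: str, magnitude: float,
                  seed: int) -> TransitionTrace:
    """Apply one defect to a trace, returning a new trace (pure function).

    ``magnitude`` semantics per defect: jagged = noise CV; bimodal = second
    mode height as a fraction of the apex; tailing = exponential tail time
    constant in units of an eighth of the boundary width (~sigma);
    interference = co-eluting peak height fraction; background = constant
    offset fraction of the apex; rt_shift = apex displacement in minutes;
    low_standard = intensity divisor. Magnitude 0 returns the trace
    unchanged.
    """
    if defect not in DEFECT_ORDER:
        raise UnknownDefect(defect)
    if magnitude == 0:
        return replace_trace(trace, trace.intensities.copy())
    rng = np.random.default_rng(seed)
    t, y = trace.times, trace.intensities.astype(float).copy()
    if trace.has_boundaries:
        width = trace.boundary_end - trace.boundary_start
        center = 0.5 * (trace.boundary_start + trace.boundary_end)
    else:
        width = t[-1] - t[0]
        center = float(t[np.argmax(y)])
    apex_height = y.max()
    if defect == "jagged":
        y = y * (1.0 + magnitude * rng.standard_normal(len(y)))
    elif defect == "bimodal":
        # second mode far and narrow enough to leave a real valley
        offset = 0.4 * width * (1 if rng.random() < 0.5 else -1)
        mode_sigma = width / 14.0
        y = y + magnitude * apex_height * np.exp(
            -0.5 * ((t - (center + offset)) / mode_sigma) ** 2)
    elif defect == "tailing":
        tau = magnitude * width / 8.0
        dt = float(np.median(np.diff(t)))
        kernel_t = np.arange(0, 6 * tau + dt, dt)
        kernel = np.exp(-kernel_t / tau)
        kernel /= kernel.sum()
        smeared = np.convolve(y, kernel)[: len(y)]
        peak = smeared.max()
        y = smeared * (apex_height / peak) if peak > 0 else smeared
    elif defect == "interference":
        offset = 0.3 * width * (1 if rng.random() < 0.5 else -1)
        interf_sigma = width / 6.0
        height = magnitude * apex_height * rng.uniform(0.7, 1.3)
        y = y + height * np.exp(-0.5 * ((t - (center + offset)) / interf_sigma) ** 2)
    elif defect == "background":
        y = y + magnitude * apex_height
    elif defect == "rt_shift":
        shift = magnitude * (1 if rng.random() < 0.5 else -1)
        y = np.interp(t - shift, t, y, left=y[0], right=y[-1])
    elif defect == "low_standard":
        y = y / magnitude
    return replace_trace(trace, np.clip(y, 0.0, None))


def replace_trace(trace: TransitionTrace, intensities: np.ndarray) -> TransitionTrace:
    return TransitionTrace(key=trace.key, times=trace.times.copy(),
                           intensities=intensities,
                           boundary_start=trace.boundary_start,
                           boundary_end=trace.boundary_end)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    traces: list
    boundaries: list
    ground_truth: pd.DataFrame   # key columns + per-defect magnitude + Status
    config: SimulationConfig

    @property
    def annotations(self) -> pd.DataFrame:
        """Ground truth reduced to the annotation-table schema."""
        return self.ground_truth[["FileName", "PeptideModifiedSequence",
                                  "PrecursorCharge", "FragmentIon",
                                  "ProductCharge", "Status"]].copy()


_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def _peptide_name(rng: np.random.Generator, index: int) -> str:
    body = "".join(_RESIDUES[i] for i in rng.integers(0, len(_RESIDUES), 8))
    return f"{body}{'KR'[index % 2]}"


def simulate_dataset(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """Generate a full multi-run dataset with ground-truth labels.

    Light and heavy traces of a fragment share apex and shape up to the
    label intensity scale unless a defect says otherwise; boundaries are
    apex +/- 4 sigma, shared across the peak group.
    """
    config = config or SimulationConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_design, rng_defects = [np.random.default_rng(s) for s in root.spawn(2)]

    # panel design (fixed across runs)
    peptides = []
    for p in range(config.n_peptides):
        name = _peptide_name(rng_design, p)
        apex = float(rng_design.uniform(*config.rt_range))
        fractions = rng_design.dirichlet(np.full(config.fragments_per_peptide, 3.0))
        scale = config.endo_scale * float(
            rng_design.lognormal(0.0, config.peptide_scale_sd))
        fragments = [(f"y{4 + i}", 1) for i in range(config.fragments_per_peptide)]
        peptides.append(dict(name=name, apex=apex, fractions=fractions,
                             scale=scale, fragments=fragments))

    run_ids = [f"run{r + 1:02d}" for r in range(config.n_runs)]
    run_factor = {r: float(rng_design.lognormal(0.0, config.run_scale_sd))
                  for r in run_ids}
    run_jitter = {r: {p["name"]: float(rng_design.normal(0.0, config.run_rt_jitter))
                      for p in peptides} for r in run_ids}

    sigma, tau = config.sigma, config.tau_over_sigma * config.sigma
    traces: list[TransitionTrace] = []
    boundary_rows: list[BoundaryTableRow] = []
    gt_rows: list[dict] = []
    defect_names = list(DEFECT_ORDER)

    for run in run_ids:
        for pep in peptides:
            apex = pep["apex"] + run_jitter[run][pep["name"]]
            b_start, b_end = apex - 4 * sigma, apex + 4 * sigma
            grid = np.arange(b_start - 2 * sigma, b_end + 2 * sigma,
                             config.sampling_interval)
            shape = _emg_shape(grid, apex, sigma, tau)
            boundary_rows.append(BoundaryTableRow(run, pep["name"], b_start, b_end))

            # group-level defect: weak standard for the whole peptide
            low_std_cfg = config.defects.get("low_standard", DefectConfig())
            group_low_std = rng_defects.random() < low_std_cfg.probability
            low_std_mag = (low_std_cfg.magnitude
                           * float(rng_defects.uniform(0.8, 1.25)))

            for f_idx, (frag, pq) in enumerate(pep["fragments"]):
                # fragment-level defects, shared by both labels where the
                # physics is shared (chromatography), endo-only otherwise
                applied: dict[str, float] = {}
                for name in ("jagged", "bimodal", "tailing", "interference",
                             "background", "rt_shift"):
                    dcfg = config.defects.get(name, DefectConfig())
                    if rng_defects.random() < dcfg.probability:
                        applied[name] = dcfg.magnitude * float(
                            rng_defects.uniform(0.8, 1.25))
                if group_low_std:
                    applied["low_standard"] = low_std_mag
                defect_seeds = {name: int(rng_defects.integers(0, 2**31))
                                for name in defect_names}
                noise_seeds = {lab: int(rng_defects.integers(0, 2**31))
                               for lab in ("endo", "std")}

                for label, lab_key in ((Label.ENDOGENOUS, "endo"),
                                       (Label.STANDARD, "std")):
                    scale = pep["scale"] * pep["fractions"][f_idx] * run_factor[run]
                    if label is Label.STANDARD:
                        scale *= config.std_scale_factor
                    y = scale * shape
                    key = TransitionKey(run, pep["name"], 2, frag, pq, label)
                    tr = TransitionTrace(key=key, times=grid, intensities=y,
                                         boundary_start=b_start, boundary_end=b_end)
                    for name in DEFECT_ORDER:
                        if name not in applied:
                            continue
                        if name == "interference" and label is not Label.ENDOGENOUS:
                            continue
                        if name == "low_standard" and label is not Label.STANDARD:
                            continue
                        tr = inject_defect(tr, name, applied[name],
                                           seed=defect_seeds[name])
                    # baseline detector noise on every trace
                    nrng = np.random.default_rng(noise_seeds[lab_key])
                    noisy = (tr.intensities
                             * (1.0 + config.base_noise_cv * nrng.standard_normal(len(grid)))
                             + config.noise_floor * nrng.standard_normal(len(grid)))
                    tr = replace_trace(tr, np.clip(noisy, 0.0, None))
                    traces.append(tr)

                flagged = any(
                    applied.get(name, 0.0) >= config.defects[name].visible_threshold
                    for name in applied)
                row = {"FileName": run, "PeptideModifiedSequence": pep["name"],
                       "PrecursorCharge": 2, "FragmentIon": frag,
                       "ProductCharge": pq,
                       "Status": "flag" if flagged else "ok"}
                for name in defect_names:
                    row[f"defect_{name}"] = applied.get(name, 0.0)
                gt_rows.append(row)

    gt = pd.DataFrame(gt_rows).sort_values(
        ["FileName", "PeptideModifiedSequence", "PrecursorCharge",
         "FragmentIon", "ProductCharge"], kind="mergesort").reset_index(drop=True)
    return SimulatedDataset(traces=traces, boundaries=boundary_rows,
                            ground_truth=gt, config=config)


def simulate_feature_table(n_pairs: int, seed: int = 0,
                           n_noise_features: int = 6,
                           label_noise_sd: float = 0.1) -> pd.DataFrame:
    """Tabular classifier-validation set: flag status is a noisy threshold
    on two informative features.

    Two standard-normal scores drive quality (think "modality up, pair
    similarity down"); a pair is flagged iff their sum plus N(0,
    ``label_noise_sd``) annotation noise exceeds 0. The remaining columns
    are uninformative noise. Rows carry synthetic run ids so grouped CV is
    exercised. This isolates the learner from the feature definitions: any
    competent classifier should recover the threshold rule almost up to the
    label noise.

    The default annotation-noise level puts the Bayes-optimal rule at
    roughly 98% accuracy, the regime annotated MRM training sets operate
    in (inter-analyst agreement 80-95% before reconciliation, reconciled
    labels supporting models in the mid-90s).
    """
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n_pairs)
    x2 = rng.standard_normal(n_pairs)
    score = x1 + x2 + label_noise_sd * rng.standard_normal(n_pairs)
    df = pd.DataFrame({
        "FileName": [f"run{1 + i % 8:02d}" for i in range(n_pairs)],
        "PeptideModifiedSequence": [f"PEPTIDE{i // 4}K" for i in range(n_pairs)],
        "PrecursorCharge": 2,
        "FragmentIon": [f"y{4 + i % 4}" for i in range(n_pairs)],
        "ProductCharge": 1,
        "modality.score.transition.endo": x1,
        "similarity.pair.transition_pair": -x2,
    })
    from .features import feature_names
    informative = {"modality.score.transition.endo",
                   "similarity.pair.transition_pair"}
    spare = [n for n in feature_names() if n not in informative]
    for name in spare[:n_noise_features]:
        df[name] = rng.standard_normal(n_pairs)
    df["Status"] = np.where(score > 0, "flag", "ok")
    return df


def write_dataset(dataset: SimulatedDataset, outdir,
                  dialect: Optional[DialectConfig] = None) -> dict[str, Path]:
    """Write chromatograms.tsv, boundaries.csv, ground_truth.csv and
    annotations.csv in the standard dialect; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "chromatograms": outdir / "chromatograms.tsv",
        "boundaries": outdir / "boundaries.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "annotations": outdir / "annotations.csv",
    }
    write_chromatograms(paths["chromatograms"], dataset.traces, dialect)
    write_boundaries(paths["boundaries"], dataset.boundaries, dialect)
    write_table(paths["ground_truth"], dataset.ground_truth)
    write_table(paths["annotations"], dataset.annotations)
    return paths
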