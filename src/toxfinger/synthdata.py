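"""Synthetic inputs with the statistical structure of high-throughput
screening and nontarget-screening data.

The generators make every pipeline stage testable without external
databases:

* chemicals as binary fingerprint vectors with heterogeneous per-bit
  prevalences, correlated duplicate blocks (to exercise the correlation
  filter), and a planted set of "toxicophore" bits that drive activity;
* per-endpoint binary labels via a logistic model in the toxicophore-bit
  count, calibrated by bisection to a target active fraction (defaults:
  2000 chemicals per endpoint and 10% actives, within the 0.5k–8k sample
  sizes and 0.1%–50% imbalance typical of large HTS collections);
* concentration–response series over the tested range (log10 of
  0.1–100 uM) — hill curves plus Gaussian noise for actives, pure noise
  for inactives;
* replicate probabilistic fingerprints per compound with a long-tailed
  replicate count (mean ~8, range 1–67, at most 10 candidates per
  spectrum) and Beta-distributed per-bit posterior probabilities whose
  post-binarization flip rate is <= 0.05 at defaults;
* an MS1 feature table with known-good/known-bad exemplars for every
  prioritization filter, along with its ground-truth retained set.

Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import CalibrationError, PreconditionError
from .fpkit import FingerprintMatrix
from .toxcurate import DoseResponseSeries, hill_curve
from .toxfp_predict import ReplicateFingerprintSet

# MAD of a zero-mean normal is 0.6745 sigma; BMAD = 3 MAD, cutoff = 6 BMAD
NORMAL_MAD = float(norm.ppf(0.75))


def implied_cutoff(noise_sd: float, bmad_multiplier: float = 3.0,
                   cutoff_multiplier: float = 6.0) -> float:
    """Efficacy cutoff implied by the baseline noise level."""
    return cutoff_multiplier * bmad_multiplier * NORMAL_MAD * noise_sd


@dataclass
class SynthSpec:
    """Study conditions for the synthetic world.

    Toxicophore bits co-occur through a latent scaffold indicator rather
    than independently, and ``label_beta`` is steep, so labels are close to
    deterministic in the toxicophore count — matching the premise that
    well-modeled endpoints are highly learnable from structure.
    """

    n_chemicals: int = 2000
    n_bits: int = 256
    n_toxicophore_bits: int = 10
    # toxicophore bits co-occur on scaffold-bearing chemicals: prevalence
    # is high given the latent toxic scaffold and low otherwise, the way a
    # structural alert lights up several related substructure bits at once
    scaffold_fraction: float | None = None  # None -> active_fraction
    toxicophore_prev_scaffold: float = 0.9
    toxicophore_prev_background: float = 0.05
    active_fraction: float = 0.10
    label_beta: float = 12.0
    n_endpoints: int = 4
    n_targets: int = 2
    dose_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(-1.0, 2.0, 8)
    )
    n_replicates_per_conc: int = 2
    n_baseline: int = 30
    noise_sd: float = 1.0
    # Beta parameters for Platt-probability emulation; Beta(8,2)/Beta(2,8)
    # give a post-binarization flip probability of ~0.02 per bit
    beta_one: tuple = (8.0, 2.0)
    beta_zero: tuple = (2.0, 8.0)
    replicate_log_mean: float = 1.79  # ln 6; lognormal mean ~8 after sigma
    replicate_log_sd: float = 0.8
    min_replicates: int = 1
    max_replicates: int = 67
    max_candidates_per_spectrum: int = 10
    n_duplicate_blocks: int = 3
    duplicate_block_size: int = 5
    background_beta: tuple = (1.2, 5.0)
    id_prefix: str = "DTXSID"
    seed: int = 0

    def __post_init__(self):
        if self.n_toxicophore_bits > self.n_bits:
            raise PreconditionError(
                "n_toxicophore_bits cannot exceed n_bits"
            )
        if not (0.0 < self.active_fraction <= 0.5):
            raise PreconditionError("active_fraction must be in (0, 0.5]")
        for name in ("n_chemicals", "n_bits", "n_endpoints", "n_targets"):
            if getattr(self, name) <= 0:
                raise PreconditionError(f"{name} must be positive")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))

    def endpoint_ids(self) -> list[str]:
        return [f"EP{i:03d}" for i in range(self.n_endpoints)]

    def target_map(self) -> dict:
        """Endpoints assigned round-robin to targets."""
        return {
            ep: f"TARGET{i % self.n_targets}"
            for i, ep in enumerate(self.endpoint_ids())
        }


def gen_chemicals(spec: SynthSpec) -> tuple[FingerprintMatrix, list]:
    """Binary fingerprints for the chemical universe plus the planted
    toxicophore bit list.

    Background bits get Beta-distributed prevalences (some below the 5%
    variability cutoff by construction); ``n_duplicate_blocks`` blocks of
    exact column copies exercise the correlation filter.  Toxicophore bits
    co-occur: a latent toxic-scaffold indicator (prevalence
    ``scaffold_fraction``) raises each toxicophore bit's conditional
    prevalence to ``toxicophore_prev_scaffold``, emulating structural
    alerts that activate several related substructure bits on the same
    molecule.  Their pairwise correlation stays well below the 95%
    correlation screen, so all planted bits survive preprocessing.
    """
    rng = spec.rng(1)
    n, m = spec.n_chemicals, spec.n_bits
    bit_ids = [f"bit{i:04d}" for i in range(m)]

    tox_idx = rng.choice(m, size=spec.n_toxicophore_bits, replace=False)
    tox_set = set(int(i) for i in tox_idx)

    prevalence = rng.beta(*spec.background_beta, size=m)
    prevalence = np.clip(prevalence, 0.005, 0.95)

    values = (rng.uniform(size=(n, m)) < prevalence).astype(float)

    scaffold_frac = (spec.scaffold_fraction
                     if spec.scaffold_fraction is not None
                     else spec.active_fraction)
    scaffold = rng.uniform(size=n) < scaffold_frac
    tox_cols = sorted(tox_set)
    per_chem_prev = np.where(
        scaffold[:, None],
        spec.toxicophore_prev_scaffold,
        spec.toxicophore_prev_background,
    )
    values[:, tox_cols] = (
        rng.uniform(size=(n, len(tox_cols))) < per_chem_prev
    ).astype(float)

    # duplicate blocks: copies of a base background column
    non_tox = [i for i in range(m) if i not in tox_set]
    rng.shuffle(non_tox)
    pos = 0
    for _ in range(spec.n_duplicate_blocks):
        block = non_tox[pos:pos + spec.duplicate_block_size]
        pos += spec.duplicate_block_size
        if len(block) < 2:
            break
        base = block[0]
        # give the base column healthy variability so the block survives
        # stage 1 and is dropped by the correlation screen
        col = (rng.uniform(size=n) < 0.3).astype(float)
        for j in block:
            values[:, j] = col

    smarts = {b: f"[synthetic-SMARTS:{b}]" for b in bit_ids}
    fpm = FingerprintMatrix(
        sample_ids=[f"{spec.id_prefix}{i:07d}" for i in range(n)],
        bit_ids=bit_ids,
        values=values,
        mode_tag="binary",
        smarts=smarts,
    )
    toxicophore_bits = [bit_ids[i] for i in sorted(tox_set)]
    return fpm, toxicophore_bits


def gen_endpoint_labels(
    fpm: FingerprintMatrix,
    toxicophore_bits: list,
    spec: SynthSpec,
    endpoint_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary activity labels and latent potencies for one endpoint.

    Activity probability is logistic(alpha + beta·count) in the number of
    toxicophore bits a chemical carries; alpha is calibrated by bisection
    so the expected active fraction equals the spec target, and the
    realized fraction must land within ±20% relative of the target.
    Actives get a latent AC50 drawn uniformly from the tested
    concentration range.
    """
    rng = spec.rng(100 + endpoint_index)
    idx = [fpm.bit_ids.index(b) for b in toxicophore_bits]
    count = fpm.values[:, idx].sum(axis=1)
    beta = spec.label_beta
    target = spec.active_fraction

    def mean_prob(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + beta * count)))))

    lo, hi = -500.0, 500.0
    if not (mean_prob(lo) <= target <= mean_prob(hi)):
        raise CalibrationError(
            f"target active fraction {target} unreachable"
        )
    alpha = brentq(lambda a: mean_prob(a) - target, lo, hi, xtol=1e-10)

    prob = 1.0 / (1.0 + np.exp(-(alpha + beta * count)))
    labels = (rng.uniform(size=len(prob)) < prob).astype(int)
    realized = labels.mean()
    # +-20% relative at study scale; small universes additionally get a
    # 3-standard-error binomial sampling allowance
    slack = max(0.2 * target,
                3.0 * np.sqrt(target * (1 - target) / len(labels)))
    if not (target - slack <= realized <= target + slack):
        raise CalibrationError(
            f"realized active fraction {realized:.4f} outside tolerance "
            f"of target {target}"
        )
    grid = spec.dose_grid
    potency = np.full(len(labels), np.nan)
    span = grid.max() - grid.min()
    potency[labels == 1] = rng.uniform(
        grid.min() + 0.15 * span, grid.max() - 0.15 * span,
        size=int(labels.sum()),
    )
    return labels, potency


def gen_dose_response(
    chemical_ids: list,
    labels: np.ndarray,
    potencies: np.ndarray,
    spec: SynthSpec,
    endpoint_id: str = "EP000",
) -> list[DoseResponseSeries]:
    """Concentration–response series for one endpoint.

    Actives follow a hill curve with top 3–12× the noise-implied cutoff,
    midpoint at the latent AC50 and slope in [0.5, 3], plus Gaussian
    noise; inactives and all baselines are pure noise.
    """
    rng = spec.rng(200 + zlib.crc32(endpoint_id.encode()) % 10000)
    cutoff = implied_cutoff(spec.noise_sd)
    grid = np.repeat(spec.dose_grid, spec.n_replicates_per_conc)
    series = []
    for cid, label, pot in zip(chemical_ids, labels, potencies):
        baseline = rng.normal(0.0, spec.noise_sd, size=spec.n_baseline)
        noise = rng.normal(0.0, spec.noise_sd, size=len(grid))
        if label == 1:
            tp = rng.uniform(3.0, 12.0) * cutoff
            gw = rng.uniform(0.5, 3.0)
            resp = hill_curve(grid, tp, pot, gw) + noise
        else:
            resp = noise
        series.append(
            DoseResponseSeries(
                chemical_id=cid,
                endpoint_id=endpoint_id,
                concs=grid.copy(),
                responses=resp,
                baseline_responses=baseline,
            )
        )
    return series


def flip_probability(a: float, b: float) -> float:
    """Probability that a Beta(a,b) posterior falls on the wrong side of
    the 0.5 binarization threshold (mass below 0.5 for a 'present' bit)."""
    from scipy.stats import beta as beta_dist

    return float(beta_dist.cdf(0.5, a, b))


def gen_replicate_fingerprints(
    true_fpm: FingerprintMatrix,
    spec: SynthSpec,
    stream: int = 300,
) -> list[ReplicateFingerprintSet]:
    """Noisy replicate probabilistic fingerprints per compound.

    Replicate counts follow a rounded lognormal (mean ~8) clipped to
    [1, 67]; replicates are packed into spectra of at most 10 candidates.
    Per bit, the posterior probability is Beta(8,2) when the true bit is 1
    and Beta(2,8) when it is 0, so binarization at 0.5 recovers the truth
    with ~98% per-bit agreement.
    """
    rng = spec.rng(stream)
    a1, b1 = spec.beta_one
    a0, b0 = spec.beta_zero
    cap = spec.max_candidates_per_spectrum
    repsets = []
    for i, cid in enumerate(true_fpm.sample_ids):
        n_rep = int(np.clip(
            round(rng.lognormal(spec.replicate_log_mean,
                                spec.replicate_log_sd)),
            max(1, spec.min_replicates), spec.max_replicates,
        ))
        truth = true_fpm.values[i].astype(bool)
        probs = np.where(
            truth[None, :],
            rng.beta(a1, b1, size=(n_rep, len(truth))),
            rng.beta(a0, b0, size=(n_rep, len(truth))),
        )
        spectrum_ids = []
        ranks = []
        for r in range(n_rep):
            spectrum_ids.append(f"{cid}_s{r // cap}")
            ranks.append(r % cap + 1)
        fpm = FingerprintMatrix(
            sample_ids=[f"{cid}#{r}" for r in range(n_rep)],
            bit_ids=list(true_fpm.bit_ids),
            values=probs,
            mode_tag="probabilistic",
        )
        repsets.append(
            ReplicateFingerprintSet(
                feature_id=cid,
                spectrum_ids=spectrum_ids,
                candidate_ranks=ranks,
                fingerprints=fpm,
                max_candidates_per_spectrum=cap,
            )
        )
    return repsets


def gen_nts_table(spec: SynthSpec) -> tuple[pd.DataFrame, set]:
    """MS1 feature table with positive and negative exemplars for every
    prioritization filter, plus the ground-truth retained feature set.

    Each exemplar family is jittered in m/z (within 1 ppm) and RT so
    grouping logic is exercised away from exact equality.
    """
    rng = spec.rng(400)

    def jit_mz(mz):
        return mz * (1.0 + rng.uniform(-0.5e-6, 0.5e-6))

    rows = []
    truth_retained = set()

    def add(fid, mz, rt, shape, sn, blank_ratio, adduct, mode,
            score=np.nan, target=False, retained=False):
        area = 1e6
        rows.append(
            {
                "feature_id": fid,
                "mz": mz,
                "rt": rt,
                "max_sample_area": area,
                "blank_area": area / blank_ratio if blank_ratio else 0.0,
                "peak_shape": shape,
                "sn": sn,
                "adduct": adduct,
                "mode": mode,
                "spectral_match_score": score,
                "target_match": target,
            }
        )
        if retained:
            truth_retained.add(fid)

    # clean molecular ion plus its sodium adduct (componentized away)
    base_mz = 301.1410
    rt = 10.0 + rng.uniform(-0.05, 0.05)
    add("F_clean", jit_mz(base_mz), rt, 0.95, 50.0, 20.0, "[M+H]+",
        "pos", retained=True)
    add("F_clean_na", jit_mz(base_mz + 21.981942), rt + 0.1, 0.9, 40.0,
        20.0, "[M+Na]+", "pos", retained=False)
    # quality failures
    add("F_badshape", jit_mz(210.1020), 5.0, 0.7, 50.0, 20.0, "[M+H]+",
        "pos", retained=False)
    add("F_badsn", jit_mz(220.1100), 6.0, 0.95, 8.0, 20.0, "[M+H]+",
        "pos", retained=False)
    add("F_blank", jit_mz(230.1200), 7.0, 0.95, 50.0, 2.0, "[M+H]+",
        "pos", retained=False)
    add("F_heavy", jit_mz(701.3000), 8.0, 0.95, 50.0, 20.0, "[M+H]+",
        "pos", retained=False)
    # identified features bypass the shape/SN screen
    add("F_target", jit_mz(240.1300), 9.0, 0.5, 5.0, 20.0, "[M+H]+",
        "pos", target=True, retained=True)
    add("F_match2a", jit_mz(250.1400), 11.0, 0.5, 5.0, 20.0, "[M+H]+",
        "pos", score=90.0, retained=True)
    add("F_match3", jit_mz(260.1500), 12.0, 0.3, 4.0, 20.0, "[M+H]+",
        "pos", score=60.0, retained=True)
    # negative-mode clean feature
    add("F_negclean", jit_mz(299.0560), 13.0, 0.92, 30.0, 20.0, "[M-H]-",
        "neg", retained=True)

    return pd.DataFrame(rows), truth_retained


def simulate_all(spec: SynthSpec, outdir: str | Path) -> dict:
    """Write every input format the pipeline consumes plus a truth/
    directory; returns row counts per artifact."""
    from .fpkit import write_smarts_sidecar
    from .io_core import write_dose_response, write_table
    from .toxfp_predict import replicate_sets_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)

    fpm, tox_bits = gen_chemicals(spec)
    fpm.write_tsv(outdir / "fingerprints.tsv")
    write_smarts_sidecar(fpm.smarts, outdir / "smarts.tsv")
    (truth_dir / "toxicophore_bits.txt").write_text(
        "\n".join(tox_bits) + "\n"
    )

    counts = {"chemicals": len(fpm.sample_ids)}
    label_rows = []
    dr_series = []
    for k, ep in enumerate(spec.endpoint_ids()):
        labels, pot = gen_endpoint_labels(fpm, tox_bits, spec,
                                          endpoint_index=k)
        for cid, y in zip(fpm.sample_ids, labels):
            label_rows.append(
                {"chemical_id": cid, "endpoint_id": ep, "hitc": int(y)}
            )
        dr_series.extend(
            gen_dose_response(fpm.sample_ids, labels, pot, spec,
                              endpoint_id=ep)
        )
    write_table(pd.DataFrame(label_rows), truth_dir / "labels.tsv")
    write_dose_response(dr_series, outdir / "dose_response.tsv")
    counts["dose_response_series"] = len(dr_series)

    target_map = spec.target_map()
    write_table(
        pd.DataFrame(
            sorted(target_map.items()), columns=["endpoint_id", "target_id"]
        ),
        outdir / "target_map.tsv",
    )

    repsets = gen_replicate_fingerprints(fpm, spec)
    replicate_sets_to_frame(repsets).to_csv(
        outdir / "replicate_fingerprints.tsv", sep="\t", index=False
    )
    counts["replicate_fingerprints"] = sum(r.n_replicates for r in repsets)

    nts, retained = gen_nts_table(spec)
    write_table(nts, outdir / "nts_features.tsv")
    (truth_dir / "nts_retained.txt").write_text(
        "\n".join(sorted(retained)) + "\n"
    )
    counts["nts_features"] = len(nts)
    return counts
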