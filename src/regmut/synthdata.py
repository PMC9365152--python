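"""Synthetic cohorts with planted ground truth for end-to-end validation.

The generator emulates the structure of the real inputs — megabase
windows, chromatin-accessibility (CA) tracks of cancer and normal
tissues, early/late replication-timing (RT) tracks, somatic SNVs with
per-SNV signature probabilities, gene annotations and a cancer-gene
list — with every latent quantity recorded, so recovery of planted
effects can be asserted by tests rather than assumed.

Generative model
----------------
A latent accessibility field ``L`` and an independent replication-timing
field ``R`` are drawn per window (standard normal). Each CA track is
``a * L + noise`` with a class-specific loading ``a`` — cancer tracks
load more strongly than normal tracks, mirroring the observation that
cancer epigenomes track regional mutagenesis more closely; noise tracks
have ``a = 0``. RT tracks are ``+/- R + noise``, positive for late
phases and negative for early ones. Regional burden has log-mean
``b0 - b_ca * L + b_rt * R`` (open chromatin depletes mutations, late
replication enriches them); counts are negative-binomial (regional
burden is overdispersed relative to Poisson), planted hotspot windows
multiply the mean by a constant factor, and each SNV draws a true
signature from window-modulated exposures with an emitted probability
vector equal to the exact posterior under the generating mixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .burden import BurdenVector
from .grid import RT_PHASES, TrackProfile, WindowGrid, build_windows

DEFAULT_COHORT = "SYN"

#: Substitution categories (pyrimidine reference convention).
CATEGORIES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Per-signature distributions over substitution categories. SBS1-like is
#: dominated by C>T deamination, SBS5-like is broad (clock-like), and
#: SBS13-like is APOBEC-style C>G heavy. The six pyrimidine categories
#: collapse the 96 trinucleotide channels real attributions use, so the
#: distributions are kept sharp to preserve a comparable level of
#: posterior confidence per SNV.
DEFAULT_CHANNELS = {
    "SBS1": (0.01, 0.01, 0.92, 0.02, 0.02, 0.02),
    "SBS5": (0.28, 0.02, 0.20, 0.12, 0.26, 0.12),
    "SBS13": (0.10, 0.80, 0.04, 0.02, 0.02, 0.02),
}
DEFAULT_EXPOSURES = {"SBS1": 0.3, "SBS5": 0.4, "SBS13": 0.3}
#: Spatial modulation of exposures: log-weight per unit of the latent
#: accessibility field, giving signatures distinct regional preferences.
DEFAULT_SIG_GAMMA = {"SBS1": 0.0, "SBS5": -0.1, "SBS13": 0.1}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for later recovery checks."""

    seed: int
    params: dict = dc_field(default_factory=dict)
    track_effects: dict[str, float] = dc_field(default_factory=dict)
    latent_ca: np.ndarray | None = None
    latent_rt: np.ndarray | None = None
    expected_burden: np.ndarray | None = None
    hotspot_windows: np.ndarray = dc_field(default_factory=lambda: np.array([], int))
    hotspot_factor: float = 1.0
    cancer_genes: list[str] = dc_field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": self.params,
            "track_effects": self.track_effects,
            "latent_ca": None if self.latent_ca is None else self.latent_ca.tolist(),
            "latent_rt": None if self.latent_rt is None else self.latent_rt.tolist(),
            "expected_burden": None
            if self.expected_burden is None
            else self.expected_burden.tolist(),
            "hotspot_windows": self.hotspot_windows.tolist(),
            "hotspot_factor": self.hotspot_factor,
            "cancer_genes": self.cancer_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            params=d["params"],
            track_effects=d["track_effects"],
            latent_ca=None if d["latent_ca"] is None else np.array(d["latent_ca"]),
            latent_rt=None if d["latent_rt"] is None else np.array(d["latent_rt"]),
            expected_burden=None
            if d["expected_burden"] is None
            else np.array(d["expected_burden"]),
            hotspot_windows=np.array(d["hotspot_windows"], dtype=int),
            hotspot_factor=d["hotspot_factor"],
            cancer_genes=list(d["cancer_genes"]),
        )


def generate_chrom_sizes(
    n_chroms: int = 5, chrom_length: int = 100_000_000
) -> dict[str, int]:
    return {f"chr{i + 1}": chrom_length for i in range(n_chroms)}


def generate_grid(
    n_chroms: int = 5,
    chrom_length: int = 100_000_000,
    window_size: int = 1_000_000,
    fraction_low_mappability: float = 0.0,
    seed: int = 0,
) -> WindowGrid:
    """Regular grid with mappability drawn high (0.85-1.0), optionally
    planting a fraction of low-mappability (<=0.8) windows."""
    grid = build_windows(generate_chrom_sizes(n_chroms, chrom_length), window_size)
    rng = np.random.default_rng(seed)
    mapp = rng.uniform(0.85, 1.0, size=len(grid))
    n_low = int(round(fraction_low_mappability * len(grid)))
    if n_low:
        low = rng.choice(len(grid), size=n_low, replace=False)
        mapp[low] = rng.uniform(0.5, 0.8, size=n_low)
    return grid.with_mappability(mapp)


def generate_tracks(
    grid: WindowGrid,
    n_cancer: int = 20,
    n_normal: int = 20,
    n_rt: int = 6,
    n_noise: int = 0,
    a_cancer: float = 1.0,
    a_normal: float = 0.4,
    a_rt: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[list[TrackProfile], SyntheticTruth]:
    """CA and RT tracks tied to shared latent fields.

    Cancer and normal CA tracks load on the same latent accessibility
    field with class-specific strength (``a_cancer > a_normal`` by
    default); noise tracks have zero loading. RT tracks pair early
    phases (negative sign) with late phases (positive sign) on an
    independent RT field. ``track_effects`` records each track's signed
    association with the burden log-mean.
    """
    rng = np.random.default_rng(seed)
    n = len(grid)
    if truth is None:
        truth = SyntheticTruth(seed=seed)
    L = rng.standard_normal(n)
    R = rng.standard_normal(n)
    truth.latent_ca = L
    truth.latent_rt = R
    truth.params.update(
        dict(
            n_cancer=n_cancer,
            n_normal=n_normal,
            n_rt=n_rt,
            n_noise=n_noise,
            a_cancer=a_cancer,
            a_normal=a_normal,
            a_rt=a_rt,
            noise_sd=noise_sd,
        )
    )
    tracks: list[TrackProfile] = []

    def add(track_id, klass, tissue, values, effect, rt_phase=None):
        tracks.append(
            TrackProfile(
                track_id=track_id,
                feature_class=klass,
                tissue=tissue,
                values=values,
                rt_phase=rt_phase,
            )
        )
        truth.track_effects[track_id] = effect

    for i in range(n_cancer):
        v = a_cancer * L + rng.normal(scale=noise_sd, size=n)
        add(f"cancerCA_{i:02d}", "cancer_CA", f"tumor_{i:02d}", v, -a_cancer)
    for i in range(n_normal):
        v = a_normal * L + rng.normal(scale=noise_sd, size=n)
        add(f"normalCA_{i:02d}", "normal_CA", f"normal_{i:02d}", v, -a_normal)
    for i in range(n_noise):
        v = rng.normal(scale=noise_sd, size=n)
        add(f"noiseCA_{i:02d}", "normal_CA", f"noise_{i:02d}", v, 0.0)
    for i in range(n_rt):
        phase = RT_PHASES[i % len(RT_PHASES)]
        late = phase in ("S3", "S4", "G2")
        sign = 1.0 if late else -1.0
        v = sign * a_rt * R + rng.normal(scale=noise_sd, size=n)
        add(
            f"RT_{phase}_{i:02d}",
            "RT",
            f"cellline_{i // len(RT_PHASES):02d}",
            v,
            sign * a_rt,
            rt_phase=phase,
        )
    return tracks, truth


def _pick_hotspots(
    grid: WindowGrid, mu: np.ndarray, n_hotspots: int, rng: np.random.Generator
) -> np.ndarray:
    """Hotspot windows drawn away from chromosome ends (first and last
    window of each chromosome excluded) to avoid edge effects, and only
    among windows with at least median baseline burden: a multiplicative
    excess on a near-empty window carries too few mutations to be
    identifiable at any scale, so planting there would measure the
    generator, not the method."""
    eligible = []
    for c in pd.unique(grid.chroms):
        idx = np.flatnonzero(grid.chroms == c)
        if len(idx) > 2:
            eligible.extend(idx[1:-1])
    eligible = np.asarray(eligible)
    eligible = eligible[mu[eligible] >= np.median(mu)]
    return np.sort(rng.choice(eligible, size=n_hotspots, replace=False))


def generate_mutations(
    grid: WindowGrid,
    truth: SyntheticTruth,
    n_samples: int = 50,
    mean_burden: float = 50.0,
    dispersion: float = 2.0,
    hotspot_factor: float = 3.0,
    n_hotspots: int = 10,
    beta_ca: float = 0.4,
    beta_rt: float = 0.25,
    exposures: dict[str, float] | None = None,
    channels: dict[str, tuple] | None = None,
    sig_gamma: dict[str, float] | None = None,
    cohort: str = DEFAULT_COHORT,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial SNVs with exact signature posteriors.

    Per window ``w`` the burden mean is
    ``mu_w = mean_burden * exp(-beta_ca * L_w + beta_rt * R_w) / norm``,
    multiplied by ``hotspot_factor`` on planted hotspot windows; total
    counts are negative binomial with the given dispersion (summed over
    samples), positions uniform within the window. Each SNV draws a true
    signature from window-modulated exposures, then a substitution
    category from the signature's channel distribution; the emitted
    probability vector is the exact posterior
    ``P(s | window, category)``, so summed probabilities per window are
    unbiased for the true per-signature counts.

    Returns (snvs, probs): the SNV table (with a ``true_signature``
    column) and the per-SNV probability table.
    """
    if truth.latent_ca is None or truth.latent_rt is None:
        raise ValueError("generate_tracks must run first (latent fields missing)")
    rng = np.random.default_rng(seed)
    exposures = dict(exposures or DEFAULT_EXPOSURES)
    channels = {k: np.asarray(v, float) for k, v in (channels or DEFAULT_CHANNELS).items()}
    sig_gamma = dict(sig_gamma or DEFAULT_SIG_GAMMA)
    sigs = sorted(exposures)
    L, R = truth.latent_ca, truth.latent_rt
    raw = np.exp(-beta_ca * L + beta_rt * R)
    mu = mean_burden * raw / raw.mean()
    if n_hotspots:
        hot = _pick_hotspots(grid, mu, n_hotspots, rng)
        mu = mu.copy()
        mu[hot] *= hotspot_factor
        truth.hotspot_windows = hot
        truth.hotspot_factor = hotspot_factor
    truth.expected_burden = mu
    truth.params.update(
        dict(
            n_samples=n_samples,
            mean_burden=mean_burden,
            dispersion=dispersion,
            hotspot_factor=hotspot_factor,
            n_hotspots=n_hotspots,
            beta_ca=beta_ca,
            beta_rt=beta_rt,
            cohort=cohort,
        )
    )
    # total count per window: sum over samples of NB(dispersion, mu/n) =
    # NB(n_samples * dispersion, mu_w)
    shape = n_samples * dispersion
    p_nb = shape / (shape + mu)
    counts = rng.negative_binomial(shape, p_nb)

    # per-window signature priors (exposures modulated along L)
    logw = np.log(np.array([exposures[s] for s in sigs]))[None, :] + np.outer(
        L, [sig_gamma[s] for s in sigs]
    )
    prior = np.exp(logw)
    prior /= prior.sum(axis=1, keepdims=True)
    chan = np.stack([channels[s] for s in sigs])  # sigs x categories

    rows = []
    prob_rows = []
    sample_ids = np.array([f"S{j:03d}" for j in range(n_samples)])
    for w in range(len(grid)):
        c = int(counts[w])
        if c == 0:
            continue
        pos = rng.integers(grid.starts[w] + 1, grid.ends[w] + 1, size=c)
        samp = sample_ids[rng.integers(0, n_samples, size=c)]
        true_s = rng.choice(len(sigs), size=c, p=prior[w])
        cats = np.array([rng.choice(6, p=chan[s]) for s in true_s])
        # posterior P(s | window, category)
        post = prior[w][None, :] * chan[:, cats].T
        post /= post.sum(axis=1, keepdims=True)
        strand_flip = rng.random(c) < 0.5
        for i in range(c):
            cat = CATEGORIES[cats[i]]
            ref, alt = cat[0], cat[2]
            if strand_flip[i]:
                ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            rows.append(
                (
                    grid.chroms[w],
                    int(pos[i]),
                    ref,
                    alt,
                    samp[i],
                    cohort,
                    sigs[true_s[i]],
                )
            )
            prob_rows.append((grid.chroms[w], int(pos[i]), samp[i], *post[i]))
    snvs = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "sample_id", "cohort", "true_signature"],
    )
    probs = pd.DataFrame(prob_rows, columns=["chrom", "pos", "sample_id", *sigs])
    # (chrom, pos, sample) must key the probability table uniquely
    dup = probs.duplicated(["chrom", "pos", "sample_id"], keep="first")
    if dup.any():
        keep = ~dup.to_numpy()
        snvs = snvs.loc[keep].reset_index(drop=True)
        probs = probs.loc[keep].reset_index(drop=True)
    return snvs, probs


def generate_genes(
    grid: WindowGrid,
    truth: SyntheticTruth,
    n_genes: int = 300,
    n_cancer_genes: int = 30,
    hotspot_bias: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Non-overlapping genes, one per sampled window, with cancer-gene
    flags preferentially on planted hotspot windows.

    Every hotspot window receives a gene (hotspots arise at genes in the
    scenario being emulated); remaining genes go to distinct random
    windows. ``n_cancer_genes`` flags are drawn without replacement with
    weight ``1 + hotspot_bias`` for genes on hotspot windows and 1
    elsewhere, so ``hotspot_bias = 0`` makes flags independent of
    hotspots.
    """
    if n_cancer_genes > n_genes:
        raise ValueError("n_cancer_genes must not exceed n_genes")
    rng = np.random.default_rng(seed)
    hot = set(truth.hotspot_windows.tolist())
    if n_genes < len(hot):
        raise ValueError("need at least one gene per hotspot window")
    others = np.setdiff1d(np.arange(len(grid)), truth.hotspot_windows)
    extra = rng.choice(others, size=n_genes - len(hot), replace=False)
    windows = np.concatenate([truth.hotspot_windows, extra]).astype(int)
    w = grid.window_size
    recs = []
    for i, win in enumerate(windows):
        length = int(rng.uniform(0.2, 0.6) * w)
        offset = int(rng.uniform(0, w - length))
        recs.append(
            {
                "gene_id": f"GENE{i:04d}",
                "chrom": grid.chroms[win],
                "start": int(grid.starts[win] + offset),
                "end": int(grid.starts[win] + offset + length),
                "window": int(win),
            }
        )
    genes = pd.DataFrame(recs)
    weights = np.where(genes["window"].isin(hot), 1.0 + hotspot_bias, 1.0)
    flagged = rng.choice(
        n_genes, size=n_cancer_genes, replace=False, p=weights / weights.sum()
    )
    genes["is_cancer_gene"] = False
    genes.loc[flagged, "is_cancer_gene"] = True
    truth.cancer_genes = sorted(genes.loc[genes["is_cancer_gene"], "gene_id"])
    truth.params.update(
        dict(n_genes=n_genes, n_cancer_genes=n_cancer_genes, hotspot_bias=hotspot_bias)
    )
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


def true_burden(snvs: pd.DataFrame, grid: WindowGrid) -> BurdenVector:
    """Observed total burden of the synthetic cohort (convenience)."""
    from .burden import count_burden

    return count_burden(snvs, grid, DEFAULT_COHORT)


def default_scenario(seed: int = 0, **overrides) -> dict:
    """The standard small study: 500 x 1 Mbp windows, 20 cancer + 20
    normal + 6 RT tracks, 50 genomes, ~50 SNVs per window, 10 hotspot
    windows at 3-fold excess.

    Returns a dict with grid, tracks, feature matrices per arm, snvs,
    probs, genes and truth. Keyword overrides are forwarded to the
    individual generators by parameter name.
    """
    from .grid import tracks_to_matrix

    grid_keys = {"n_chroms", "chrom_length", "window_size", "fraction_low_mappability"}
    track_keys = {
        "n_cancer", "n_normal", "n_rt", "n_noise",
        "a_cancer", "a_normal", "a_rt", "noise_sd",
    }
    mut_keys = {
        "n_samples", "mean_burden", "dispersion", "hotspot_factor", "n_hotspots",
        "beta_ca", "beta_rt", "exposures", "channels", "sig_gamma", "cohort",
    }
    gene_keys = {"n_genes", "n_cancer_genes", "hotspot_bias"}
    unknown = set(overrides) - grid_keys - track_keys - mut_keys - gene_keys
    if unknown:
        raise TypeError(f"unknown scenario parameters: {sorted(unknown)}")
    ss = np.random.SeedSequence(seed)
    s_grid, s_tracks, s_mut, s_genes = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    grid = generate_grid(
        seed=s_grid, **{k: v for k, v in overrides.items() if k in grid_keys}
    )
    tracks, truth = generate_tracks(
        grid, seed=s_tracks, **{k: v for k, v in overrides.items() if k in track_keys}
    )
    snvs, probs = generate_mutations(
        grid, truth, seed=s_mut, **{k: v for k, v in overrides.items() if k in mut_keys}
    )
    gene_over = {k: v for k, v in overrides.items() if k in gene_keys}
    if "n_genes" not in gene_over:
        # scale gene count to the grid so small test grids stay valid
        gene_over["n_genes"] = min(300, max(1, int(0.6 * len(grid))))
        gene_over.setdefault("n_cancer_genes", max(1, gene_over["n_genes"] // 10))
    genes = generate_genes(grid, truth, seed=s_genes, **gene_over)
    X, meta = tracks_to_matrix(tracks)
    by_class = {
        klass: [t.track_id for t in tracks if t.feature_class == klass]
        for klass in ("cancer_CA", "normal_CA", "RT")
    }
    return {
        "grid": grid,
        "tracks": tracks,
        "X": X,
        "meta": meta,
        "arms": by_class,
        "snvs": snvs,
        "probs": probs,
        "genes": genes,
        "truth": truth,
        "seed": seed,
    }


def write_dataset(scenario: dict, outdir: str | Path) -> dict[str, Path]:
    """Emit a scenario as the on-disk formats the pipeline reads."""
    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid: WindowGrid = scenario["grid"]
    paths: dict[str, Path] = {}
    sizes = {}
    for c in pd.unique(grid.chroms):
        sizes[str(c)] = int(grid.ends[grid.chroms == c].max())
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    rio.write_chrom_sizes(sizes, paths["chrom_sizes"])
    paths["grid"] = outdir / "windows.tsv"
    rio.write_grid(grid, paths["grid"])
    paths["tracks"] = outdir / "tracks"
    rio.write_track_matrix(scenario["X"], scenario["meta"], paths["tracks"])
    paths["mutations"] = outdir / "mutations.tsv"
    rio.write_mutations(scenario["snvs"], paths["mutations"])
    paths["probs"] = outdir / "signature_probabilities.tsv"
    scenario["probs"].to_csv(paths["probs"], sep="\t", index=False)
    paths["genes"] = outdir / "genes.bed"
    rio.write_genes_bed(scenario["genes"], paths["genes"])
    paths["cancer_genes"] = outdir / "cancer_genes.txt"
    rio.write_gene_list(scenario["truth"].cancer_genes, paths["cancer_genes"])
    paths["truth"] = outdir / "truth.json"
    scenario["truth"].to_json(paths["truth"])
    return paths
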