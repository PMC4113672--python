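"""Synthetic expression data and transcript sequences with planted sponge modules.

The generator embodies, as a linear-Gaussian structural model, exactly
the statistical structure the sensitivity-correlation method assumes:

* miRNA profiles Z are i.i.d. standard normal;
* a *pure sponge* triplet couples an mRNA X and a lncRNA Y to a shared
  miRNA, X = -beta*Z + eps and Y = -beta*Z + eps', so both partners are
  negatively correlated with the miRNA, X and Y are conditionally
  independent given Z, and the population sensitivity equals the full
  X-Y correlation beta^2 / (beta^2 + sigma^2);
* a *mixed TF-sponge* triplet routes the miRNA effect on the mRNA
  through a latent repressor T: T = -gamma*Z + eps, X = -delta*T + eps,
  giving a positive mRNA-miRNA correlation, with Y = -beta*Z + eps' as
  before (note corr(X, Y) < 0 in this configuration, so mixed pairs sit
  in the anti-correlated tail of the pair distribution);
* a *direct co-expression* pair couples X and Y through a latent factor
  W independent of every miRNA — high pairwise correlation but
  population sensitivity exactly zero, the confounder the method must
  reject;
* all remaining genes are independent noise.

Transcript sequences carry the mediating miRNA's 6-mer site (the DNA
reverse complement of mature positions 2-7) planted at recorded
positions in BOTH partners of every planted triplet, while every other
occurrence of any planted site is scrubbed by resampling offending
windows, so the seed scanner's ground truth is exact: perfect recall on
planted sites, zero hits on control transcripts.

All randomness flows from the single ``rng_seed``; identical configs
produce bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation, SequenceSet, ValidationError
from .seedmatch import MiRNASeed, extract_seed, find_sites

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults describe a desk-scale cohort: 200 samples, 300 mRNAs,
    60 lncRNAs and 30 miRNAs, with 20 pure sponge triplets cycling
    through 5 mediator miRNAs, 10 mixed triplets through 3 further
    mediators, 20 direct co-expression confounder pairs, unit couplings
    and unit noise. Sequence lengths keep every mRNA past the 500 nt
    3'UTR availability filter.
    """

    n_samples: int = 200
    n_mrna: int = 300
    n_lncrna: int = 60
    n_mirna: int = 30
    n_pure_triplets: int = 20
    n_mixed_triplets: int = 10
    n_direct_pairs: int = 20
    n_pure_mediators: int = 5
    n_mixed_mediators: int = 3
    beta: float = 1.0  # miRNA -> RNA coupling
    gamma: float = 1.0  # miRNA -> TF coupling (mixed modules)
    delta: float = 1.0  # TF -> mRNA coupling (mixed modules)
    alpha: float = 1.0  # latent-factor coupling (direct pairs)
    noise_sd: float = 1.0
    utr_len: int = 600
    lnc_len: int = 1200
    mature_len: int = 22
    missing_rate: float = 0.0
    count_emission: bool = False
    count_base_mean: float = 100.0
    count_dispersion: float = 10.0
    condition: str = "normal"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        n_planted = self.n_pure_triplets + self.n_mixed_triplets + self.n_direct_pairs
        if n_planted > self.n_mrna or n_planted > self.n_lncrna:
            raise ValidationError("planted modules exceed mRNA or lncRNA pool size")
        if self.n_pure_mediators + self.n_mixed_mediators > self.n_mirna:
            raise ValidationError("mediator miRNAs exceed miRNA pool size")
        if self.n_pure_triplets and self.n_pure_mediators < 1:
            raise ValidationError("pure triplets require at least one mediator")
        if self.n_mixed_triplets and self.n_mixed_mediators < 1:
            raise ValidationError("mixed triplets require at least one mediator")
        for name in ("beta", "gamma", "delta", "alpha", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.utr_len < 6 or self.lnc_len < 6:
            raise ValidationError("transcripts must be at least 6 nt")
        if self.mature_len < 7:
            raise ValidationError("mature miRNAs must be at least 7 nt")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of planted structure.

    ``triplets`` lists planted pure/mixed modules with their population
    correlations and sensitivities; ``direct_pairs`` the confounder
    pairs; ``sites`` the planted MRE positions (1-based), filled in by
    :func:`generate_sequences`.
    """

    triplets: pd.DataFrame
    direct_pairs: pd.DataFrame
    sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transcript_id", "role", "mirna", "position"]
        )
    )

    def pure_pairs(self) -> list[tuple[str, str]]:
        sub = self.triplets[self.triplets["module_type"] == "pure"]
        return list(zip(sub["mrna"], sub["lncrna"]))

    def mediators(self, module_type: str = "pure") -> list[str]:
        sub = self.triplets[self.triplets["module_type"] == module_type]
        return sorted(set(sub["mirna"]))


def _gene_ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _population_values(cfg: SyntheticConfig, module_type: str) -> dict[str, float]:
    b, g, d, s2 = cfg.beta, cfg.gamma, cfg.delta, cfg.noise_sd**2
    if module_type == "pure":
        v = b * b + s2
        return {
            "pop_r_xy": b * b / v,
            "pop_r_xz": -b / np.sqrt(v),
            "pop_r_zy": -b / np.sqrt(v),
            "pop_s": b * b / v,
        }
    # mixed: X = -delta*T + eps, T = -gamma*Z + eps, Y = -beta*Z + eps'
    var_x = d * d * (g * g + s2) + s2
    var_y = b * b + s2
    return {
        "pop_r_xy": -d * g * b / np.sqrt(var_x * var_y),
        "pop_r_xz": d * g / np.sqrt(var_x),
        "pop_r_zy": -b / np.sqrt(var_y),
        "pop_s": -d * g * b / np.sqrt(var_x * var_y),
    }


def _emit_counts(values: np.ndarray, cfg: SyntheticConfig, rng) -> np.ndarray:
    mean = cfg.count_base_mean * np.exp2(values)
    n = cfg.count_dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(float)


def generate_expression(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate (mRNA, lncRNA, miRNA) matrices plus the ground-truth ledger."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    ns = cfg.n_samples
    sd = cfg.noise_sd
    mirna_ids = _gene_ids("mir_", cfg.n_mirna)
    mrna_ids = _gene_ids("mRNA_", cfg.n_mrna)
    lnc_ids = _gene_ids("lnc_", cfg.n_lncrna)
    sample_ids = _gene_ids("S", ns)

    Z = rng.standard_normal((cfg.n_mirna, ns))
    X = sd * rng.standard_normal((cfg.n_mrna, ns))
    Y = sd * rng.standard_normal((cfg.n_lncrna, ns))

    triplet_rows = []
    cursor = 0
    for i in range(cfg.n_pure_triplets):
        mi = i % cfg.n_pure_mediators
        z = Z[mi]
        X[cursor] = -cfg.beta * z + sd * rng.standard_normal(ns)
        Y[cursor] = -cfg.beta * z + sd * rng.standard_normal(ns)
        triplet_rows.append(
            {
                "mrna": mrna_ids[cursor],
                "lncrna": lnc_ids[cursor],
                "mirna": mirna_ids[mi],
                "module_type": "pure",
                **_population_values(cfg, "pure"),
            }
        )
        cursor += 1
    for j in range(cfg.n_mixed_triplets):
        mi = cfg.n_pure_mediators + (j % cfg.n_mixed_mediators)
        z = Z[mi]
        t = -cfg.gamma * z + sd * rng.standard_normal(ns)
        X[cursor] = -cfg.delta * t + sd * rng.standard_normal(ns)
        Y[cursor] = -cfg.beta * z + sd * rng.standard_normal(ns)
        triplet_rows.append(
            {
                "mrna": mrna_ids[cursor],
                "lncrna": lnc_ids[cursor],
                "mirna": mirna_ids[mi],
                "module_type": "mixed",
                **_population_values(cfg, "mixed"),
            }
        )
        cursor += 1
    direct_rows = []
    a2 = cfg.alpha**2
    for _ in range(cfg.n_direct_pairs):
        w = rng.standard_normal(ns)
        X[cursor] = cfg.alpha * w + sd * rng.standard_normal(ns)
        Y[cursor] = cfg.alpha * w + sd * rng.standard_normal(ns)
        direct_rows.append(
            {
                "mrna": mrna_ids[cursor],
                "lncrna": lnc_ids[cursor],
                "pop_r_xy": a2 / (a2 + sd * sd),
                "pop_s": 0.0,
            }
        )
        cursor += 1

    if cfg.count_emission:
        X = _emit_counts(X, cfg, rng)
        Y = _emit_counts(Y, cfg, rng)
        Z = _emit_counts(Z, cfg, rng)
    if cfg.missing_rate > 0:
        for M in (X, Y, Z):
            M[rng.random(M.shape) < cfg.missing_rate] = np.nan

    truth = SyntheticTruth(
        pd.DataFrame(
            triplet_rows,
            columns=[
                "mrna",
                "lncrna",
                "mirna",
                "module_type",
                "pop_r_xy",
                "pop_r_xz",
                "pop_r_zy",
                "pop_s",
            ],
        ),
        pd.DataFrame(direct_rows, columns=["mrna", "lncrna", "pop_r_xy", "pop_s"]),
    )
    return (
        ExpressionMatrix(pd.DataFrame(X, index=mrna_ids, columns=sample_ids)),
        ExpressionMatrix(pd.DataFrame(Y, index=lnc_ids, columns=sample_ids)),
        ExpressionMatrix(pd.DataFrame(Z, index=mirna_ids, columns=sample_ids)),
        truth,
    )


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _occurrences(seq: str, sites) -> list[tuple[str, int]]:
    return [(site, pos - 1) for site in sites for pos in find_sites(seq, site)]


def _scrub(
    seq: np.ndarray,
    forbidden_sites,
    planted: set[tuple[str, int]],
    rng,
    max_rounds: int = 200,
) -> np.ndarray:
    """Resample windows until the only site occurrences are the planted ones."""
    protected = {
        p for _, start in planted for p in range(start, start + 6)
    }
    for _ in range(max_rounds):
        bad = [
            occ
            for occ in _occurrences("".join(seq), forbidden_sites)
            if occ not in planted
        ]
        if not bad:
            return seq
        for _, start in bad:
            free = [p for p in range(start, start + 6) if p not in protected]
            if not free:  # cannot happen: distinct sites cannot share a full window
                raise RuntimeError("forbidden site fully inside a planted window")
            pos = int(rng.choice(free))
            seq[pos] = rng.choice(_BASES[_BASES != seq[pos]])
    raise RuntimeError("site scrubbing did not converge")


def random_transcripts(
    rng, count: int, length: int, forbidden_sites, prefix: str = "ctrl_"
) -> dict[str, str]:
    """Random sequences guaranteed free of every forbidden 6-mer site."""
    forbidden = list(forbidden_sites)
    out = {}
    for i in range(count):
        seq = _scrub(_random_seq(rng, length), forbidden, set(), rng)
        out[f"{prefix}{i + 1:04d}"] = "".join(seq)
    return out


def generate_mirna_sequences(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[SequenceSet, list[MiRNASeed]]:
    """Random mature miRNA sequences with pairwise-distinct 6-mer seeds."""
    mirna_ids = _gene_ids("mir_", cfg.n_mirna)
    records: dict[str, str] = {}
    seeds: list[MiRNASeed] = []
    used: set[str] = set()
    for mid in mirna_ids:
        for _ in range(1000):
            mature = "".join(_random_seq(rng, cfg.mature_len)).replace("T", "U")
            seed = extract_seed(mid, mature)
            if seed.seed not in used:
                used.add(seed.seed)
                records[mid] = mature
                seeds.append(seed)
                break
        else:  # pragma: no cover - 4096 >> n_mirna
            raise RuntimeError("could not draw distinct seeds")
    return SequenceSet(records, "mature_mirna"), seeds


def generate_sequences(
    cfg: SyntheticConfig,
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
    seeds: list[MiRNASeed] | None = None,
) -> tuple[SequenceSet, SequenceSet, SequenceSet, list[MiRNASeed], SyntheticTruth]:
    """Emit 3'UTR, lncRNA-transcript and mature-miRNA sequence sets.

    Each planted triplet's miRNA site is inserted at a recorded position
    in both partners; every transcript is otherwise free of every
    planted site. Returns the updated truth with the site table filled.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    if seeds is None:
        mature, seeds = generate_mirna_sequences(cfg, rng)
    else:
        mature = SequenceSet({s.mirna_id: s.mature_seq for s in seeds}, "mature_mirna")
    site_of = {s.mirna_id: s.site for s in seeds}
    planted_mirnas = sorted(set(truth.triplets["mirna"]))
    missing = [m for m in planted_mirnas if m not in site_of]
    if missing:
        raise ValidationError(f"no seed provided for planted miRNA(s) {missing}")
    forbidden = sorted({site_of[m] for m in planted_mirnas})

    # transcript_id -> list of (mirna, start0)
    plant_plan: dict[tuple[str, str], list[str]] = {}
    for row in truth.triplets.itertuples(index=False):
        plant_plan.setdefault((row.mrna, "utr3"), []).append(row.mirna)
        plant_plan.setdefault((row.lncrna, "lnc_transcript"), []).append(row.mirna)

    site_rows = []

    def _make(transcript_id: str, role: str, length: int) -> str:
        seq = _random_seq(rng, length)
        planted: set[tuple[str, int]] = set()
        taken: list[int] = []
        for mirna in plant_plan.get((transcript_id, role), []):
            site = site_of[mirna]
            for _ in range(1000):
                start = int(rng.integers(0, length - 5))
                if all(abs(start - t) >= 6 for t in taken):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not place non-overlapping sites")
            seq[start : start + 6] = list(site)
            planted.add((site, start))
            taken.append(start)
            site_rows.append((transcript_id, role, mirna, start + 1))
        seq = _scrub(seq, forbidden, planted, rng)
        return "".join(seq)

    utrs = {
        gid: _make(gid, "utr3", cfg.utr_len) for gid in _gene_ids("mRNA_", cfg.n_mrna)
    }
    lncs = {
        gid: _make(gid, "lnc_transcript", cfg.lnc_len)
        for gid in _gene_ids("lnc_", cfg.n_lncrna)
    }
    sites = pd.DataFrame(
        site_rows, columns=["transcript_id", "role", "mirna", "position"]
    ).sort_values(["transcript_id", "mirna", "position"]).reset_index(drop=True)
    new_truth = SyntheticTruth(truth.triplets, truth.direct_pairs, sites)
    return (
        SequenceSet(utrs, "utr3"),
        SequenceSet(lncs, "lnc_transcript"),
        mature,
        seeds,
        new_truth,
    )


# ---------------------------------------------------------------------------
# full dataset and file bundle


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    annotation: GeneAnnotation
    utr3: SequenceSet
    lnc_tx: SequenceSet
    mature: SequenceSet
    seeds: list[MiRNASeed]
    truth: SyntheticTruth


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the full input bundle: expression, annotation, sequences, truth."""
    rng = np.random.default_rng(cfg.rng_seed)
    mrna, lncrna, mirna, truth = generate_expression(cfg, rng)
    utr3, lnc_tx, mature, seeds, truth = generate_sequences(cfg, truth, rng)
    ann_rows = (
        [(g, g, "protein_coding") for g in mrna.gene_ids]
        + [(g, g, "lncRNA") for g in lncrna.gene_ids]
        + [(g, g, "miRNA") for g in mirna.gene_ids]
    )
    annotation = GeneAnnotation(
        pd.DataFrame(ann_rows, columns=["gene_id", "symbol", "biotype"]).set_index(
            "gene_id"
        )
    )
    return SyntheticDataset(
        cfg, mrna, lncrna, mirna, annotation, utr3, lnc_tx, mature, seeds, truth
    )


def write_bundle(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the dataset as the pipeline's exact input formats.

    Emits one combined expression TSV (all biotypes), sample metadata,
    annotation, the three FASTAs, truth tables and a manifest recording
    the config and its hash. Returns name -> path.
    """
    from pathlib import Path

    from .io import write_annotation, write_expression, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    combined = ExpressionMatrix(
        pd.concat([ds.mrna.data, ds.lncrna.data, ds.mirna.data])
    )
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "annotation": outdir / "annotation.tsv",
        "mirna_fasta": outdir / "mirna_mature.fasta",
        "utr_fasta": outdir / "mrna_utr3.fasta",
        "lnc_fasta": outdir / "lncrna_transcripts.fasta",
        "truth_triplets": outdir / "truth_triplets.tsv",
        "truth_direct_pairs": outdir / "truth_direct_pairs.tsv",
        "truth_sites": outdir / "truth_sites.tsv",
        "manifest": outdir / "manifest.json",
    }
    write_expression(combined, paths["expression"])
    pd.DataFrame(
        {"sample_id": combined.sample_ids, "condition": ds.config.condition}
    ).to_csv(paths["samples"], sep="\t", index=False)
    write_annotation(ds.annotation, paths["annotation"])
    write_fasta(ds.mature, paths["mirna_fasta"])
    write_fasta(ds.utr3, paths["utr_fasta"])
    write_fasta(ds.lnc_tx, paths["lnc_fasta"])
    ds.truth.triplets.to_csv(paths["truth_triplets"], sep="\t", index=False)
    ds.truth.direct_pairs.to_csv(paths["truth_direct_pairs"], sep="\t", index=False)
    ds.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    manifest = {"config": asdict(ds.config), "config_hash": ds.config.hash()}
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
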