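"""Synthetic fixtures with known ground truth.

Generates everything the downstream pipeline consumes: a reference set of
AM-fungal OTU sequences plus non-glomeromycotinan outgroup sequences, a
randomized-complete-block field design with yields driven by the inoculum's
read share, per-sample paired amplicon reads drawn from community mixtures,
and Poisson-propagule dilution-series bioassay outcomes.

The generator emulates a three-trial soybean inoculation experiment: the
introduced inoculum's share of the root AM community declines with the
density of indigenous infective propagules (most probable number, MPN), and
grain yield responds to the inoculum's colonization share.  Every output is
a deterministic function of ``SynthConfig.seed``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import edlib

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "ReferenceSet",
    "make_reference",
    "make_design",
    "make_reads",
    "make_dilution_series",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.int8)
_INOCULUM_SAMPLE = "inoculum"


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror a 3-trial x 4-block randomized complete block design
    with two P-fertilizer levels and paired control/inoculated plots, an
    LSU-D2-sized amplicon (~360 nt), indigenous propagule densities of
    roughly 0.02 propagules/mL soil in trials 1-2 and an order of magnitude
    more in trial 3, and yields (kg/ha) that increase with the inoculum's
    read share.
    """

    n_trials: int = 3
    n_blocks: int = 4
    p_levels: tuple = (0, 100)          # kg P2O5 / ha
    n_indigenous_otus: int = 22
    n_inoculum_otus: int = 3
    n_outgroup: int = 5
    ref_length: int = 360               # nt
    read_length: int = 220              # nt per mate
    read_error_rate: float = 0.005      # per-base substitution probability
    reads_per_sample: int = 1200
    outgroup_fraction: float = 0.05     # fraction of non-AM fungal reads
    junk_fraction: float = 0.02         # fraction of unalignable reads
    # propagules / mL soil per trial; trial 3 an order of magnitude denser
    propagule_density: tuple = (0.02, 0.025, 0.2)
    # inoculum read share in inoculated plots: logistic(a - b * ln MPN)
    share_logit_a: float = -2.2
    share_logit_b: float = 0.85
    share_logit_sd: float = 0.25        # plot-level noise on the logit scale
    background_share: float = 0.05      # inoculum-type share in controls
    yield_baseline: float = 3100.0      # kg/ha
    inoculum_effect: float = 400.0      # kg/ha per unit inoculum read share
    yield_noise_sd: float = 60.0        # kg/ha
    community_concentration: float = 200.0   # Dirichlet plot-level precision
    # dilution bioassay: two-fold series 2^-1, 2^-3, 2^-5, 2^-7
    dilutions: tuple = (2**-1, 2**-3, 2**-5, 2**-7)
    n_plants_per_level: int = 4
    assay_volume_ml: float = 20.0       # soil volume per assay pot
    seed: int = 0

    def __post_init__(self):
        for name in ("n_trials", "n_blocks", "n_indigenous_otus",
                     "n_inoculum_otus", "n_outgroup", "ref_length",
                     "read_length", "reads_per_sample", "n_plants_per_level"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("read_error_rate", "outgroup_fraction", "junk_fraction",
                     "background_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.propagule_density) < self.n_trials:
            raise ValueError("need one propagule density per trial")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child generator for a fixed stream id."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class RefRecord:
    otu_id: str
    seq: str
    group: str  # "AM" or "OUT"


@dataclass
class ReferenceSet:
    """OTU and outgroup sequences, the classification target."""

    records: list

    @property
    def am_ids(self):
        return [r.otu_id for r in self.records if r.group == "AM"]

    @property
    def out_ids(self):
        return [r.otu_id for r in self.records if r.group == "OUT"]

    def get(self, otu_id: str) -> RefRecord:
        for r in self.records:
            if r.otu_id == otu_id:
                return r
        raise KeyError(otu_id)

    def to_fasta(self) -> str:
        buf = io.StringIO()
        for r in self.records:
            buf.write(f">{r.otu_id}|{r.group}\n{r.seq}\n")
        return buf.getvalue()

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        from Bio import SeqIO
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            name, _, group = rec.id.rpartition("|")
            if group not in ("AM", "OUT"):
                raise ValueError(f"reference header {rec.id!r} lacks |AM or |OUT tag")
            records.append(RefRecord(name, str(rec.seq).upper(), group))
        return cls(records)


@dataclass
class GroundTruth:
    """True quantities behind the fixtures, for assertions."""

    proportions: pd.DataFrame          # samples x AM OTUs, rows sum to 1
    inoculum_share: pd.Series          # true inoculum read share per sample
    yield_coefficients: dict           # baseline, inoculum_effect, noise sd
    propagule_density: dict            # trial -> propagules/mL


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 4, length, dtype=np.int8)


def _mutate(rng, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    # shift by 1..3 guarantees a different base
    out[hit] = (out[hit] + rng.integers(1, 4, len(hit))) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return codes.astype(np.uint8).tobytes().translate(
        bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")).decode()


def _global_identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def make_reference(config: SynthConfig, max_attempts: int = 20) -> ReferenceSet:
    """Generate AM OTU and outgroup reference sequences.

    AM sequences descend from a common random ancestor with ~15% of sites
    substituted per OTU, so any AM pair is far below the 95%-identity
    assignment criterion while an error-bearing read still matches its own
    source at ~99%.  Outgroup sequences are unrelated random sequences kept
    below 80% identity to every AM sequence.  Raises ``RuntimeError`` if the
    divergence constraints cannot be met within ``max_attempts`` redraws.
    """
    if config.ref_length < 330:
        raise ValueError("ref_length must be >= 330 nt")
    rng = config.rng(1)
    n_am = config.n_indigenous_otus + config.n_inoculum_otus

    for _ in range(max_attempts):
        ancestor = _random_seq(rng, config.ref_length)
        am_seqs = [_decode(_mutate(rng, ancestor, 0.15)) for _ in range(n_am)]
        ok = all(
            _global_identity(am_seqs[i], am_seqs[j]) < 0.92
            for i in range(n_am) for j in range(i + 1, n_am)
        )
        if ok:
            break
    else:
        raise RuntimeError("could not generate sufficiently divergent AM references")

    out_seqs = []
    for _ in range(config.n_outgroup):
        for _ in range(max_attempts):
            cand = _decode(_random_seq(rng, config.ref_length))
            if all(_global_identity(cand, s) < 0.80 for s in am_seqs):
                out_seqs.append(cand)
                break
        else:
            raise RuntimeError("could not generate divergent outgroup sequence")

    records = []
    for i in range(config.n_indigenous_otus):
        records.append(RefRecord(f"OTU_{i + 1:03d}", am_seqs[i], "AM"))
    for k in range(config.n_inoculum_otus):
        records.append(RefRecord(f"INOC_{k + 1:02d}",
                                 am_seqs[config.n_indigenous_otus + k], "AM"))
    for k, s in enumerate(out_seqs):
        records.append(RefRecord(f"NONAM_{k + 1:02d}", s, "OUT"))
    return ReferenceSet(records)


def inoculum_otu_ids(config: SynthConfig) -> list:
    """The OTU ids that make up the synthetic inoculum."""
    return [f"INOC_{k + 1:02d}" for k in range(config.n_inoculum_otus)]


def true_inoculum_share(config: SynthConfig, mpn: float, inoculated: bool,
                        logit_noise: float = 0.0) -> float:
    """Inoculum read share: logistic(a - b*ln(MPN)) for inoculated plots.

    The decreasing-in-MPN link encodes niche pre-emption by the indigenous
    community: dense indigenous propagule banks leave less root for the
    introduced fungus.  Control plots carry a small constant background
    share of inoculum-type reads (indigenous look-alikes).
    """
    if not inoculated:
        return config.background_share
    eta = config.share_logit_a - config.share_logit_b * np.log(mpn) + logit_noise
    return float(1.0 / (1.0 + np.exp(-eta)))


def make_design(config: SynthConfig) -> pd.DataFrame:
    """Field design and per-plot metadata, one row per plot.

    Columns: sample_id, trial, block, p_level, inoculated, mpn plus soil
    covariates, true_inoculum_share (ground truth), yield_kg_ha, shoot_p.
    Yield is baseline + inoculum_effect * true share + Gaussian noise.
    """
    rng = config.rng(2)
    rows = []
    for t in range(config.n_trials):
        trial = f"T{t + 1}"
        mpn = float(config.propagule_density[t])
        # trial-level soil chemistry means; plots vary around them
        pac0 = float(rng.normal(1500, 200))      # phosphate absorption coeff
        nitrate0 = float(rng.normal(10, 2))      # mg N / 100 g
        ex_k0 = float(rng.normal(30, 5))         # mg K2O / 100 g
        avail_p0 = float(rng.normal(15, 4))      # mg P2O5 / 100 g
        for b in range(config.n_blocks):
            block = f"{trial}_B{b + 1}"
            for p in config.p_levels:
                for inoculated in (False, True):
                    pac = pac0 + float(rng.normal(0, 40))
                    nitrate = max(nitrate0 + float(rng.normal(0, 0.8)), 0.1)
                    ex_k = max(ex_k0 + float(rng.normal(0, 2)), 0.1)
                    avail_p = max(avail_p0 + float(rng.normal(0, 1.5)), 0.1)
                    noise = float(rng.normal(0.0, config.share_logit_sd))
                    share = true_inoculum_share(config, mpn, inoculated, noise)
                    y = (config.yield_baseline
                         + config.inoculum_effect * (share if inoculated else 0.0)
                         + float(rng.normal(0.0, config.yield_noise_sd)))
                    shoot_p = 4.1 + 0.4 * share + float(rng.normal(0, 0.08))
                    treat = "R10" if inoculated else "CTRL"
                    rows.append({
                        "sample_id": f"{trial}_B{b + 1}_P{p}_{treat}",
                        "trial": trial,
                        "block": block,
                        "p_level": p,
                        "inoculated": inoculated,
                        "mpn": mpn,
                        "phosphate_absorption": pac,
                        "nitrate_n": nitrate,
                        "exchangeable_k": ex_k,
                        "available_p": avail_p,
                        "true_inoculum_share": share,
                        "yield_kg_ha": max(y, 0.0),
                        "shoot_p": shoot_p,
                    })
    return pd.DataFrame(rows)


_Q_GOOD, _Q_BAD = 40, 3          # Phred: error 1e-4 vs 0.5


def _apply_read_errors(rng, codes: np.ndarray, error_rate: float):
    """Substitution errors with per-base Phred-consistent qualities.

    Each base is independently "bad" with probability ``2 * error_rate``;
    bad bases carry quality Q3 (error probability 0.5) and are substituted
    accordingly, good bases carry Q40 and are left intact, so the marginal
    per-base error probability is ``error_rate`` and every quality score
    states the true error probability of its base.  The occasional run of
    bad bases at the 3' end is what the QV-threshold trimmer removes.
    """
    n = len(codes)
    if error_rate <= 0:
        return codes, chr(_Q_GOOD + 33) * n
    bad = rng.random(n) < min(2.0 * error_rate, 1.0)
    flip = bad & (rng.random(n) < 0.5)
    out = codes.copy()
    idx = np.nonzero(flip)[0]
    out[idx] = (out[idx] + rng.integers(1, 4, len(idx))) % 4
    qual = np.where(bad, _Q_BAD + 33, _Q_GOOD + 33).astype(np.uint8)
    return out, qual.tobytes().decode()


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    source: str  # source reference id, "junk" for unalignable reads


def _community_proportions(config, rng, design, am_ids, inoc_ids):
    """Per-sample true proportions over AM OTUs (rows sum to 1)."""
    n_ind = config.n_indigenous_otus
    ind_ids = [i for i in am_ids if i not in inoc_ids]
    # trial-specific base compositions: communities differ between sites
    trial_base = {}
    for trial in design["trial"].unique():
        trial_base[trial] = rng.dirichlet(np.full(n_ind, 0.5))
    props = {}
    for _, row in design.iterrows():
        base = trial_base[row["trial"]]
        plot = rng.dirichlet(base * config.community_concentration + 1e-6)
        s = row["true_inoculum_share"]
        inoc_split = rng.dirichlet(np.full(len(inoc_ids), 5.0))
        vec = np.concatenate([plot * (1.0 - s), inoc_split * s])
        props[row["sample_id"]] = vec
    cols = ind_ids + list(inoc_ids)
    df = pd.DataFrame(props, index=cols).T
    return df[am_ids]  # canonical column order


def _reads_from_template(rng, config, template_codes, read_id, source):
    """Paired reads covering the template with an overlap in the middle."""
    L = config.read_length
    n = len(template_codes)
    r1, q1 = _apply_read_errors(rng, template_codes[:L].copy(),
                                config.read_error_rate)
    r2, q2 = _apply_read_errors(rng, _revcomp_codes(template_codes[max(0, n - L):]),
                                config.read_error_rate)
    return ReadPair(read_id, _decode(r1), q1, _decode(r2), q2, source)


def make_reads(config: SynthConfig, reference: ReferenceSet,
               design: pd.DataFrame, include_inoculum_sample: bool = True):
    """Per-sample paired reads plus the ground truth behind them.

    Each field sample draws ``reads_per_sample`` read pairs: AM reads from
    the sample's true community mixture, a configurable fraction from
    outgroup references, and a junk fraction of unalignable random
    sequence.  When ``include_inoculum_sample`` is set, an extra sample
    named ``"inoculum"`` containing only inoculum-OTU reads is appended —
    the pure-culture sequencing run that defines the tracking marker.

    Returns ``(reads_by_sample, ground_truth)`` where ``reads_by_sample``
    maps sample id to a list of :class:`ReadPair`.
    """
    if config.reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be positive")
    rng = config.rng(3)
    am_ids = reference.am_ids
    inoc_ids = [i for i in inoculum_otu_ids(config) if i in am_ids]
    props = _community_proportions(config, rng, design, am_ids, inoc_ids)
    out_ids = reference.out_ids
    ref_codes = {r.otu_id: np.frombuffer(
        r.seq.encode().translate(bytes.maketrans(b"ACGT", b"\x00\x01\x02\x03")),
        dtype=np.int8) for r in reference.records}

    reads_by_sample = {}
    n = config.reads_per_sample
    n_out = int(round(n * config.outgroup_fraction)) if out_ids else 0
    n_junk = int(round(n * config.junk_fraction))
    n_am = n - n_out - n_junk

    def _sample_reads(sid, am_counts):
        reads = []
        k = 0
        for otu, cnt in am_counts.items():
            for _ in range(int(cnt)):
                reads.append(_reads_from_template(
                    rng, config, ref_codes[otu], f"{sid}_r{k:06d}", otu))
                k += 1
        for _ in range(n_out):
            otu = out_ids[rng.integers(len(out_ids))]
            reads.append(_reads_from_template(
                rng, config, ref_codes[otu], f"{sid}_r{k:06d}", otu))
            k += 1
        for _ in range(n_junk):
            tmpl = _random_seq(rng, config.ref_length)
            reads.append(_reads_from_template(
                rng, config, tmpl, f"{sid}_r{k:06d}", "junk"))
            k += 1
        return reads

    for sid in design["sample_id"]:
        counts = rng.multinomial(n_am, props.loc[sid].to_numpy())
        am_counts = dict(zip(props.columns, counts))
        reads_by_sample[sid] = _sample_reads(sid, am_counts)

    if include_inoculum_sample:
        split = rng.dirichlet(np.full(len(inoc_ids), 5.0))
        counts = rng.multinomial(n_am, split)
        reads = []
        for otu, cnt in zip(inoc_ids, counts):
            for j in range(int(cnt)):
                reads.append(_reads_from_template(
                    rng, config, ref_codes[otu],
                    f"{_INOCULUM_SAMPLE}_r{len(reads):06d}", otu))
        reads_by_sample[_INOCULUM_SAMPLE] = reads

    truth = GroundTruth(
        proportions=props,
        inoculum_share=design.set_index("sample_id")["true_inoculum_share"],
        yield_coefficients={
            "baseline": config.yield_baseline,
            "inoculum_effect": config.inoculum_effect,
            "noise_sd": config.yield_noise_sd,
        },
        propagule_density={f"T{t + 1}": float(config.propagule_density[t])
                           for t in range(config.n_trials)},
    )
    return reads_by_sample, truth


def write_fastq_pair(reads, r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}/1\n{r.seq1}\n+\n{r.qual1}\n")
            f2.write(f"@{r.read_id}/2\n{r.seq2}\n+\n{r.qual2}\n")


def make_dilution_series(config: SynthConfig) -> pd.DataFrame:
    """Dilution-series bioassay outcomes per trial x block.

    Each assay pot is positive with probability 1 - exp(-lambda*d*v) where
    lambda is the trial's true propagule density (propagules/mL), d the
    dilution factor and v the assay soil volume (mL) — the Poisson
    single-propagule infection model behind MPN estimation.
    """
    rng = config.rng(4)
    rows = []
    for t in range(config.n_trials):
        lam = float(config.propagule_density[t])
        if lam <= 0:
            raise ValueError("propagule densities must be > 0")
        for b in range(config.n_blocks):
            # small block-to-block heterogeneity in the propagule bank
            lam_b = lam * float(np.exp(rng.normal(0.0, 0.15)))
            for d in config.dilutions:
                p = 1.0 - np.exp(-lam_b * d * config.assay_volume_ml)
                pos = int(rng.binomial(config.n_plants_per_level, p))
                rows.append({
                    "trial": f"T{t + 1}",
                    "block": f"T{t + 1}_B{b + 1}",
                    "dilution": d,
                    "volume_ml": config.assay_volume_ml,
                    "n_tested": config.n_plants_per_level,
                    "n_positive": pos,
                })
    return pd.DataFrame(rows)


def config_to_yaml(config: SynthConfig) -> str:
    import yaml
    d = asdict(config)
    d["p_levels"] = list(d["p_levels"])
    d["propagule_density"] = [float(x) for x in d["propagule_density"]]
    d["dilutions"] = [float(x) for x in d["dilutions"]]
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> SynthConfig:
    import yaml
    d = yaml.safe_load(text)
    for key in ("p_levels", "propagule_density", "dilutions"):
        if key in d:
            d[key] = tuple(d[key])
    return SynthConfig(**d)
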