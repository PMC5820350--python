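"""Synthetic-data generators for every input the pipeline consumes.

Every pipeline input can be generated here with the statistical structure
the analysis assumes: multi-mode escape spectra whose aggregate follows the
two-state model, stability series with replicate noise, paired-end 2x150 bp
plasmid-population read sets at ~7200x depth with insertion/SNP-disrupted
molecules mixed at model-driven frequencies, and logistic microplate OD
traces.  All sequences are synthetic (random under a fixed seed) and all
generators are deterministic given their seed; a ground-truth ledger
accompanies stochastic outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fitting import StabilitySeries
from .growth import ODSeries
from .isscan.align import ReadSet
from .isscan.breakpoints import InsertionEvent
from .isscan.references import ISCatalog, ISElement, PlasmidReference, revcomp
from .popmodel import ModelParams, producer_fraction

__all__ = [
    "EscapeMode",
    "EscapeSpectrum",
    "GeneratorTruth",
    "simulate_spectrum_frequencies",
    "simulate_stability_series",
    "make_reference",
    "make_catalog",
    "build_disrupted_sequence",
    "simulate_reads",
    "simulate_od",
    "default_spectrum",
    "DEFAULT_TIMEPOINTS",
]

#: Default sequencing emulation profile: a laboratory-simulated
#: scale-up fermentation sequenced by 2x150 bp paired-end reads at ~7200x.
DEFAULT_DEPTH = 7200
DEFAULT_READ_LEN = 150
DEFAULT_INSERT_MEAN = 300.0
DEFAULT_INSERT_SD = 60.0
DEFAULT_ERROR_RATE = 0.003
#: Five sampling points across a ~70-generation simulated fermentation.
DEFAULT_TIMEPOINTS = (0.0, 18.0, 35.0, 53.0, 70.0)

# mobile-element subgroups emulated by default: (length, genomic copies)
_DEFAULT_SUBGROUPS = {
    "IS10": (1329, 3),
    "IS186": (1343, 4),
    "IS5": (1195, 13),
    "IS1": (768, 8),
    "IS2": (1331, 12),
    "IS3": (1258, 5),
    "IS30": (1221, 4),
    "IS150": (1443, 4),
    "IS4": (1426, 1),
    "tn1000": (2000, 1),
}


@dataclass(frozen=True)
class EscapeMode:
    """One escape channel: an IS insertion event or a pathway SNP, with its
    per-generation rate.  All modes confer full load alleviation."""

    label: str
    rate: float
    event: InsertionEvent | None = None
    variant: tuple[int, str] | None = None  # (1-based position, alt base)

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("mode escape rate must be non-negative")
        if (self.event is None) == (self.variant is None):
            raise ValueError("a mode carries exactly one of event or variant")


@dataclass(frozen=True)
class EscapeSpectrum:
    """A set of escape modes sharing one production load; the aggregate
    dynamics equal the single-mode model at k = sum of mode rates."""

    load: float
    modes: tuple[EscapeMode, ...]

    @property
    def k_total(self) -> float:
        return sum(m.rate for m in self.modes)

    @property
    def params(self) -> ModelParams:
        return ModelParams(load=self.load, escape_rate=self.k_total)


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground-truth ledger: per-generation intact fraction and per-mode
    population frequencies.  Frequencies sum with the intact fraction to 1."""

    generations: np.ndarray
    intact: np.ndarray
    mode_freqs: dict  # label -> np.ndarray over generations
    spectrum: EscapeSpectrum
    seed: int | None = None

    def at(self, g: float) -> dict:
        """Frequencies at one grid point, as {label: frequency} plus
        'intact'."""
        i = int(np.argmin(np.abs(self.generations - g)))
        out = {"intact": float(self.intact[i])}
        for label, arr in self.mode_freqs.items():
            out[label] = float(arr[i])
        return out


def simulate_spectrum_frequencies(spectrum: EscapeSpectrum, grid) -> GeneratorTruth:
    """Closed-form per-mode population frequencies.

    Each mode i obeys dN_i/dg = mu N_i + k_i P, giving
    N_i / P = (k_i / (c + K)) (e^{(c+K) g} - 1) with K the summed rate; the
    aggregate non-producer fraction equals the single-mode model at k = K.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid < 0):
        raise ValueError("generations must be non-negative")
    c, K = spectrum.load, spectrum.k_total
    if not spectrum.modes or K == 0.0:
        return GeneratorTruth(
            generations=grid,
            intact=np.ones_like(grid),
            mode_freqs={m.label: np.zeros_like(grid) for m in spectrum.modes},
            spectrum=spectrum,
        )
    ck = c + K
    # overflow-safe shared factor: ratio_i = (k_i/ck) expm1(ck g)
    x = ck * grid
    expm1x = np.where(x < 700, np.expm1(np.minimum(x, 700)), np.inf)
    total_ratio = (K / ck) * expm1x
    intact = np.where(np.isinf(total_ratio), 0.0, 1.0 / (1.0 + total_ratio))
    mode_freqs = {}
    for m in spectrum.modes:
        share = m.rate / K
        with np.errstate(invalid="ignore"):
            freq = np.where(
                np.isinf(total_ratio),
                share,  # limit: intact fraction 0, modes split by rate share
                (m.rate / ck) * expm1x * intact,
            )
        mode_freqs[m.label] = freq
    return GeneratorTruth(generations=grid, intact=intact, mode_freqs=mode_freqs, spectrum=spectrum)


def simulate_stability_series(
    params: ModelParams | EscapeSpectrum,
    grid,
    noise_sd: float = 0.0,
    n_reps: int = 5,
    seed: int = 0,
    observable_kind: str = "relative_titer",
) -> StabilitySeries:
    """Replicate-mean stability series with additive Gaussian noise.

    The noiseless observable is f(g)/f(g_ref) (relative titer, reference =
    earliest grid point) or 1 - f(g) (mobile-element fraction).
    """
    if noise_sd < 0 or n_reps < 1:
        raise ValueError("noise_sd must be >= 0 and n_reps >= 1")
    if isinstance(params, EscapeSpectrum):
        params = params.params
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    f = producer_fraction(params, grid)
    if observable_kind == "relative_titer":
        y_true = f / producer_fraction(params, float(grid.min()))
    elif observable_kind == "mobile_element_fraction":
        y_true = 1.0 - f
    else:
        raise ValueError(f"unknown observable kind {observable_kind!r}")
    rng = np.random.default_rng(seed)
    reps = y_true[None, :] + noise_sd * rng.standard_normal((n_reps, grid.size))
    mean = reps.mean(axis=0)
    sem = reps.std(axis=0, ddof=1) / math.sqrt(n_reps) if n_reps > 1 else np.zeros_like(mean)
    return StabilitySeries(
        generations=grid,
        values=np.clip(mean, 0.0, None),
        sem=sem,
        n_reps=np.full(grid.size, n_reps),
        observable_kind=observable_kind,
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_reference(seed: int = 7, length: int = 7064, name: str = "pSYN-MVA") -> PlasmidReference:
    """Synthetic ~7 kb circular production-plasmid reference with a
    three-gene pathway operon annotation (synthetic stand-in sequence; the
    coordinates echo an atoB/ERG13/tHMGR-like operon layout)."""
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, length)
    annotations = {
        "atoB": (500, 1684),
        "ERG13": (1750, 3225),
        "tHMGR": (3280, 4750),
    }
    return PlasmidReference(name=name, seq=seq, annotations=annotations)


def make_catalog(seed: int = 11, subgroups: dict | None = None) -> ISCatalog:
    """Synthetic mobile-element catalog (random sequences under a fixed
    seed, labelled with the emulated subgroup names and genomic copy
    numbers)."""
    rng = np.random.default_rng(seed)
    subgroups = _DEFAULT_SUBGROUPS if subgroups is None else subgroups
    els = []
    for name, (length, copies) in subgroups.items():
        els.append(ISElement(name=name, seq=_random_seq(rng, length), copy_number=copies))
    return ISCatalog(els, merge_rules={})


def default_spectrum(
    ref: PlasmidReference,
    catalog: ISCatalog,
    load: float = 0.281,
    k_total: float = 2.1e-7,
    seed: int = 23,
) -> EscapeSpectrum:
    """Default escape spectrum: four IS insertions in the early pathway
    genes plus one SNP mode, rates summing to ``k_total``."""
    rng = np.random.default_rng(seed)
    shares = (0.40, 0.30, 0.15, 0.10, 0.05)
    specs = [
        ("IS10", 1200, "+"),
        ("IS186", 2500, "-"),
        ("IS5", 900, "+"),
        ("IS1", 2900, "+"),
    ]
    modes = []
    for (sub, pos, orient), share in zip(specs, shares):
        tsd = int(rng.integers(3, 13))
        ev = InsertionEvent(position=pos, subgroup=sub, orientation=orient, tsd_length=tsd)
        modes.append(EscapeMode(label=f"{sub}@{pos}", rate=share * k_total, event=ev))
    snp_pos = 1000
    ref_base = ref.seq[snp_pos - 1]
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    modes.append(
        EscapeMode(label=f"SNP@{snp_pos}{ref_base}>{alt}", rate=shares[-1] * k_total,
                   variant=(snp_pos, alt))
    )
    return EscapeSpectrum(load=load, modes=tuple(modes))


def build_disrupted_sequence(
    ref: PlasmidReference, event: InsertionEvent, catalog: ISCatalog
) -> str:
    """Linearised sequence of a plasmid molecule carrying one IS insertion
    with target-site duplication.

    With position p (last reference base before the element) and TSD length
    t, the molecule is ref[1..p] + element + ref[p-t+1..L]: the t target
    bases appear on both sides of the element.
    """
    p, t = event.position, event.tsd_length
    L = len(ref)
    if not (t >= 0 and t < p <= L):
        raise ValueError(f"event coordinates (position {p}, tsd {t}) outside reference")
    elem = catalog[event.subgroup].seq
    if event.orientation == "-":
        elem = revcomp(elem)
    return ref.seq[:p] + elem + ref.seq[p - t :]


def apply_snp(ref: PlasmidReference, position: int, alt: str) -> str:
    """Reference sequence with a single substitution at a 1-based position."""
    if not 1 <= position <= len(ref):
        raise ValueError("SNP position outside reference")
    return ref.seq[: position - 1] + alt + ref.seq[position:]


def simulate_reads(
    ref: PlasmidReference,
    truth_point: dict,
    catalog: ISCatalog,
    spectrum: EscapeSpectrum,
    depth: float = DEFAULT_DEPTH,
    read_len: int = DEFAULT_READ_LEN,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> tuple[ReadSet, dict]:
    """Paired-end reads from a mixture of intact and disrupted molecules.

    ``truth_point`` maps 'intact' and mode labels to molecule frequencies
    (e.g. from :meth:`GeneratorTruth.at`).  Fragments are sampled uniformly
    on each circular molecule with normal insert sizes; both mates are
    returned as plus/minus-strand reads with uniform substitution errors.
    Read names carry an ``origin=`` provenance tag; the returned ledger
    records molecule-of-origin fragment counts and the seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    labels = ["intact"] + [m.label for m in spectrum.modes]
    weights = np.array([max(float(truth_point.get(l, 0.0)), 0.0) for l in labels])
    if weights.sum() <= 0:
        raise ValueError("truth point has no positive molecule frequencies")
    weights = weights / weights.sum()
    molecules = {"intact": ref.seq}
    for m in spectrum.modes:
        if m.event is not None:
            molecules[m.label] = build_disrupted_sequence(ref, m.event, catalog)
        else:
            molecules[m.label] = apply_snp(ref, *m.variant)
    doubled = {l: s + s for l, s in molecules.items()}
    lengths = {l: len(s) for l, s in molecules.items()}

    rng = np.random.default_rng(seed)
    n_pairs = int(round(depth * len(ref) / (2.0 * read_len)))
    # fragments are drawn per base, not per molecule: a disrupted molecule
    # is longer than the intact plasmid and yields proportionally more
    # fragments at equal molar frequency
    mass = weights * np.array([lengths[l] for l in labels], dtype=float)
    mol_idx = rng.choice(len(labels), size=n_pairs, p=mass / mass.sum())
    inserts = np.clip(
        np.round(rng.normal(insert_mean, insert_sd, n_pairs)).astype(int),
        read_len,
        None,
    )
    starts = rng.random(n_pairs)
    names, seqs = [], []
    ledger_counts = dict.fromkeys(labels, 0)
    for i in range(n_pairs):
        label = labels[mol_idx[i]]
        L_mol = lengths[label]
        ins = min(int(inserts[i]), L_mol)
        s = int(starts[i] * L_mol)
        frag = doubled[label][s : s + ins]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        names.append(f"frag{i}/1|origin={label}")
        seqs.append(r1)
        names.append(f"frag{i}/2|origin={label}")
        seqs.append(r2)
        ledger_counts[label] += 1

    if error_rate > 0:
        n_err = rng.binomial(read_len, error_rate, size=len(seqs))
        shift = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        for j in np.nonzero(n_err)[0]:
            s = list(seqs[j])
            for pos in rng.integers(0, len(s), n_err[j]):
                base = s[pos]
                s[pos] = shift.get(base, "ACGT")[rng.integers(0, 3)]
            seqs[j] = "".join(s)

    reads = ReadSet(names, seqs, quals=["I" * read_len] * len(seqs))
    ledger = {
        "seed": seed,
        "n_pairs": n_pairs,
        "depth": depth,
        "read_len": read_len,
        "error_rate": error_rate,
        "molecule_fragments": ledger_counts,
        "molecule_frequencies": dict(zip(labels, weights.tolist())),
        "fragment_sampling_probabilities": dict(zip(labels, (mass / mass.sum()).tolist())),
    }
    return reads, ledger


def simulate_od(
    rate: float,
    carrying_capacity: float = 10.0,
    od0: float = 0.002,
    duration_h: float = 16.0,
    sampling_min: float = 10.0,
    noise_sd: float = 0.02,
    background: float = 0.04,
    n_blanks: int = 3,
    seed: int = 0,
) -> ODSeries:
    """Logistic growth curve sampled every ``sampling_min`` minutes with
    multiplicative noise and an additive blank background.

    The default carrying capacity (10 OD units, far above the 0.04-0.4
    analysis band) keeps the band in near-pure exponential phase, so the
    band-mean rate matches the generating rate to ~2%; lower capacities
    emulate visible logistic slowdown.
    """
    if rate <= 0:
        raise ValueError("growth rate must be positive")
    rng = np.random.default_rng(seed)
    t_min = np.arange(0.0, duration_h * 60.0 + 0.5 * sampling_min, sampling_min)
    t_h = t_min / 60.0
    K = carrying_capacity
    od_true = K / (1.0 + (K / od0 - 1.0) * np.exp(-rate * t_h))
    od_noisy = od_true * (1.0 + noise_sd * rng.standard_normal(t_min.size))
    blanks = background + 0.001 * rng.standard_normal((n_blanks, t_min.size))
    od_raw = od_noisy + blanks.mean(axis=0)
    return ODSeries(times_min=t_min, od_raw=od_raw, blanks=blanks)
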