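"""Gradient-transcriptome simulator with planted co-expression structure.

The generator emulates the study design the pipeline targets: an ordered
developmental gradient of 11 sections (immature base to mature tip of a
growing monocot leaf), a handful of anchor genes with smooth gradient
profiles standing in for the guide genes, "planted" partner genes built to
a prescribed correlation with their anchor, and a background of independent
noise genes. Every output is directly consumable by the pipeline, and the
planted truth allows recovery scoring (sensitivity, specificity, sign
accuracy).

Planting uses the classical construction y = rho * z + sqrt(1 - rho^2) * e
on the standardized scale, where z is the standardized anchor profile and
e is independent Gaussian noise with standard deviation ``noise_sd``; the
result is shifted to nonnegativity (an affine map, so correlations are
untouched). With noise_sd = 1 the population correlation equals the target
rho exactly; in general it is rho / sqrt(rho^2 + (1 - rho^2) * noise_sd^2).
At |rho| = 1 the noise term vanishes and the sample correlation is exactly
+/-1 for every seed.

Randomness contract: a single root seed drives per-gene substreams derived
by stable hashing of the gene id, so adding or removing a gene never
perturbs any other gene's profile and identical specs reproduce the
dataset bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from guidecoex.correlation import pearson_correlation
from guidecoex.io import ExpressionMatrix, GuideGeneSet, TFFamilyAnnotation
from guidecoex.network import CandidateReport, CoexNetwork

__all__ = [
    "AnchorSpec",
    "PlantedSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "GeneratedDataset",
    "RecoveryScore",
    "default_study_spec",
    "generate_anchor_profile",
    "generate_dataset",
    "plant_correlated_gene",
    "score_recovery",
    "write_dataset",
]

_PROFILE_KINDS = ("increasing", "decreasing", "peaked")


@dataclass(frozen=True)
class AnchorSpec:
    anchor_id: str
    kind: str = "increasing"
    amplitude: float = 100.0


@dataclass(frozen=True)
class PlantedSpec:
    gene_id: str
    anchor_id: str
    target_rho: float
    family: str


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset.

    noise_sd scales the orthogonal noise in planted genes and the profiles
    of background genes (standardized units). background_families is cycled
    over the background genes; a None entry leaves the gene unannotated,
    emulating non-TF genes in the matrix.
    """

    anchors: list[AnchorSpec]
    planted: list[PlantedSpec] = field(default_factory=list)
    n_background: int = 0
    background_families: list[Optional[str]] = field(default_factory=list)
    n_sections: int = 11
    noise_sd: float = 1.0
    noise_model: str = "gaussian"  # or "lognormal" for background genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sections < 3:
            raise ValueError("n_sections must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for p in self.planted:
            if abs(p.target_rho) > 1:
                raise ValueError(f"|target_rho| must be <= 1, got {p.target_rho}")
        ids = (
            [a.anchor_id for a in self.anchors]
            + [p.gene_id for p in self.planted]
            + self.background_ids
        )
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(g for g in ids if g in seen or seen.add(g))
            raise ValueError(f"duplicate gene id in spec: {dup!r}")
        anchor_ids = {a.anchor_id for a in self.anchors}
        for p in self.planted:
            if p.anchor_id not in anchor_ids:
                raise ValueError(f"planted gene {p.gene_id!r} references unknown anchor")

    @property
    def background_ids(self) -> list[str]:
        return [f"BG_{i:04d}" for i in range(self.n_background)]


@dataclass
class SyntheticTruth:
    """Planted targets plus the correlation each planted gene actually realized."""

    planted_map: dict[str, tuple[str, float, str]]  # gene -> (anchor, rho, family)
    realized_r: dict[str, float]
    background_ids: list[str] = field(default_factory=list)


@dataclass
class GeneratedDataset:
    matrix: ExpressionMatrix
    guides: GuideGeneSet
    annotation: TFFamilyAnnotation
    truth: SyntheticTruth


@dataclass
class RecoveryScore:
    """Recovery of planted structure by the pipeline network.

    sensitivity: fraction of eligible planted genes (|target rho| above the
    network threshold) present in the network; None when no gene is
    eligible. specificity: fraction of background genes absent from the
    network; None without background. sign_accuracy: fraction of recovered
    planted genes whose edge sign matches sign(target rho); None when
    nothing was recovered.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    sign_accuracy: Optional[float]
    n_eligible: int = 0
    n_recovered: int = 0


def _gene_rng(root_seed: int, gene_id: str) -> np.random.Generator:
    """Independent, platform-stable substream for one gene."""
    digest = hashlib.sha256(gene_id.encode("utf-8")).digest()
    sub = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([root_seed & 0x7FFFFFFF, sub]))


def generate_anchor_profile(
    kind: str, n_sections: int, amplitude: float, seed: int
) -> np.ndarray:
    """A nonnegative, non-constant gradient profile of length n_sections.

    "increasing" is strictly monotone increasing up to ``amplitude``;
    "decreasing" is the exact reverse of "increasing" with the same seed;
    "peaked" is unimodal with a single interior local maximum.
    """
    if n_sections < 3:
        raise ValueError("n_sections must be >= 3")
    if kind not in _PROFILE_KINDS:
        raise ValueError(f"invalid profile kind {kind!r}; expected one of {_PROFILE_KINDS}")
    rng = np.random.default_rng(seed)
    if kind in ("increasing", "decreasing"):
        increments = rng.uniform(0.5, 1.5, size=n_sections)
        profile = amplitude * np.cumsum(increments) / np.sum(increments)
        return profile[::-1].copy() if kind == "decreasing" else profile
    # peaked: Gaussian bump with an interior, off-grid center (no ties)
    center = rng.uniform(n_sections / 3, 2 * n_sections / 3)
    width = n_sections / 4
    idx = np.arange(n_sections, dtype=float)
    return amplitude * np.exp(-((idx - center) ** 2) / (2 * width**2))


def _standardize(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    sd = float(np.sqrt(np.mean(xc * xc)))
    if sd == 0.0:
        raise ValueError("constant anchor profile")
    return xc / sd


def _shift_nonneg(y: np.ndarray) -> np.ndarray:
    m = float(y.min())
    return y - m if m < 0 else y


def plant_correlated_gene(
    anchor: np.ndarray, target_rho: float, noise_sd: float, seed: int
) -> np.ndarray:
    """A nonnegative profile with prescribed correlation to ``anchor``.

    See the module docstring for the construction; at |target_rho| = 1 the
    sample correlation equals sign(target_rho) exactly.
    """
    if abs(target_rho) > 1:
        raise ValueError(f"|target_rho| must be <= 1, got {target_rho}")
    z = _standardize(np.asarray(anchor, dtype=float))
    if abs(target_rho) == 1.0:
        return _shift_nonneg(target_rho * z)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_sd if noise_sd > 0 else 0.0, size=z.size)
    y = target_rho * z + np.sqrt(1.0 - target_rho**2) * eps
    return _shift_nonneg(y)


def _background_profile(
    rng: np.random.Generator, n: int, noise_sd: float, model: str
) -> np.ndarray:
    if model == "lognormal":
        return rng.lognormal(mean=1.0, sigma=max(noise_sd, 1e-12), size=n)
    return _shift_nonneg(rng.normal(0.0, noise_sd, size=n))


def generate_dataset(spec: SyntheticSpec) -> GeneratedDataset:
    """Matrix, guide set, family annotation and planted truth from a spec.

    Anchors come first (and double as the guide set), then planted genes,
    then background genes. Identical specs produce bit-identical output.
    """
    n = spec.n_sections
    rows: dict[str, np.ndarray] = {}

    anchor_profiles: dict[str, np.ndarray] = {}
    for a in spec.anchors:
        a_seed = int(_gene_rng(spec.seed, a.anchor_id).integers(0, 2**31 - 1))
        profile = generate_anchor_profile(a.kind, n, a.amplitude, a_seed)
        anchor_profiles[a.anchor_id] = profile
        rows[a.anchor_id] = profile

    assignments: dict[str, str] = {}
    planted_map: dict[str, tuple[str, float, str]] = {}
    realized: dict[str, float] = {}
    for p in spec.planted:
        g_seed = int(_gene_rng(spec.seed, p.gene_id).integers(0, 2**31 - 1))
        profile = plant_correlated_gene(
            anchor_profiles[p.anchor_id], p.target_rho, spec.noise_sd, g_seed
        )
        rows[p.gene_id] = profile
        assignments[p.gene_id] = p.family
        planted_map[p.gene_id] = (p.anchor_id, p.target_rho, p.family)
        r = pearson_correlation(anchor_profiles[p.anchor_id], profile)
        realized[p.gene_id] = float("nan") if r is None else r

    bg_ids = spec.background_ids
    for i, gene in enumerate(bg_ids):
        rng = _gene_rng(spec.seed, gene)
        rows[gene] = _background_profile(rng, n, spec.noise_sd, spec.noise_model)
        if spec.background_families:
            fam = spec.background_families[i % len(spec.background_families)]
            if fam is not None:
                assignments[gene] = fam

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    matrix = ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    )
    guides = GuideGeneSet([(a.anchor_id, a.anchor_id) for a in spec.anchors])
    annotation = TFFamilyAnnotation(assignments)
    truth = SyntheticTruth(
        planted_map=planted_map, realized_r=realized, background_ids=list(bg_ids)
    )
    return GeneratedDataset(matrix=matrix, guides=guides, annotation=annotation, truth=truth)


def score_recovery(
    truth: SyntheticTruth,
    candidates: list[CandidateReport],
    network: CoexNetwork,
) -> RecoveryScore:
    """Score how well the network recovered the planted structure.

    A planted gene is eligible when |target rho| exceeds the network
    threshold and its family matches the network's family filter; it is
    recovered when it appears as a TF node. Sign accuracy
    compares the edge to the gene's own anchor (falling back to the
    majority sign of its edges if that particular edge is absent) against
    sign(target rho).
    """
    tau = network.threshold_used.tau if network.threshold_used else 0.0
    in_net = set(network.tf_ids)
    fam_filter = network.family_filter
    eligible = [
        g
        for g, (_, rho, fam) in truth.planted_map.items()
        if abs(rho) > tau and (fam_filter == "all" or fam == fam_filter)
    ]
    recovered = [g for g in eligible if g in in_net]
    sensitivity = len(recovered) / len(eligible) if eligible else None

    if truth.background_ids:
        n_bg_in = sum(1 for g in truth.background_ids if g in in_net)
        specificity = 1.0 - n_bg_in / len(truth.background_ids)
    else:
        specificity = None

    if recovered:
        correct = 0
        for g in recovered:
            anchor, rho, _ = truth.planted_map[g]
            want = "positive" if rho > 0 else "negative"
            edge = network.edge(anchor, g)
            if edge is not None:
                got = edge.sign
            else:
                signs = [e.sign for e in network.edges_of_tf(g)]
                got = max(set(signs), key=signs.count)
            correct += got == want
        sign_accuracy: Optional[float] = correct / len(recovered)
    else:
        sign_accuracy = None

    return RecoveryScore(
        sensitivity=sensitivity,
        specificity=specificity,
        sign_accuracy=sign_accuracy,
        n_eligible=len(eligible),
        n_recovered=len(recovered),
    )


# Guide symbols of the emulated study design, used by default_study_spec.
STUDY_GUIDE_SYMBOLS = [
    "OsGI",
    "Ghd7",
    "Hd1",
    "Ehd1",
    "RFT1",
    "Hd3a",
    "OsMADS14",
    "OsMADS15",
]


def default_study_spec(
    seed: int = 0,
    rho: float = 0.95,
    n_background: int = 400,
    n_sections: int = 11,
    noise_sd: float = 1.0,
) -> SyntheticSpec:
    """The study-condition default scenario.

    Eight anchors named after the photoperiodic flowering guides, all
    rising along the 11-section maturation gradient (so they are mutually
    positively correlated, as co-regulated pathway genes on a gradient
    are). The G2-like complement consists of 28 planted TFs - 21 at
    +rho and 7 at -rho, assigned round-robin to the anchors - mirroring
    the network structure the screen is meant to find. Other TF families
    (MYB, bHLH, NAC, WRKY, ERF) are planted in decreasing numbers so the
    family ranking has a realistic shape with G2-like on top, and the
    background holds unannotated genes plus TFs of unrelated families
    with independent noise profiles.
    """
    anchors = [
        AnchorSpec(sym, "increasing", amplitude=20.0 * (i + 1))
        for i, sym in enumerate(STUDY_GUIDE_SYMBOLS)
    ]
    planted: list[PlantedSpec] = []
    for i in range(21):
        planted.append(
            PlantedSpec(
                f"SYN_G2L_P{i + 1:02d}",
                STUDY_GUIDE_SYMBOLS[i % 8],
                rho,
                "G2-like",
            )
        )
    for i in range(7):
        planted.append(
            PlantedSpec(
                f"SYN_G2L_N{i + 1:02d}",
                STUDY_GUIDE_SYMBOLS[i % 8],
                -rho,
                "G2-like",
            )
        )
    other = [("MYB", 10), ("bHLH", 8), ("NAC", 6), ("WRKY", 5), ("ERF", 4)]
    for fam, count in other:
        for i in range(count):
            sign = 1.0 if i % 3 else -1.0
            planted.append(
                PlantedSpec(
                    f"SYN_{fam}_{i + 1:02d}",
                    STUDY_GUIDE_SYMBOLS[(i * 3) % 8],
                    sign * (rho - 0.03),
                    fam,
                )
            )
    background_families: list[Optional[str]] = [
        None,
        "C2H2",
        None,
        "HSF",
        None,
        "GRAS",
        None,
        "Trihelix",
    ]
    return SyntheticSpec(
        anchors=anchors,
        planted=planted,
        n_background=n_background,
        background_families=background_families,
        n_sections=n_sections,
        noise_sd=noise_sd,
        seed=seed,
    )


def write_dataset(dataset: GeneratedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit matrix/guides/families/truth files in the formats the readers accept."""
    from guidecoex.io import write_expression_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "guides": out / "guides.tsv",
        "families": out / "families.tsv",
        "truth": out / "truth.tsv",
    }
    write_expression_matrix(dataset.matrix, paths["matrix"])
    with paths["guides"].open("w", encoding="utf-8") as fh:
        for sym, gid in dataset.guides.entries:
            fh.write(f"{sym}\t{gid}\n")
    with paths["families"].open("w", encoding="utf-8") as fh:
        for gene, fam in dataset.annotation.assignments.items():
            fh.write(f"{gene}\t{fam}\n")
    with paths["truth"].open("w", encoding="utf-8") as fh:
        fh.write("gene_id\tanchor_id\ttarget_rho\tfamily\trealized_r\n")
        for gene, (anchor, rho, fam) in dataset.truth.planted_map.items():
            fh.write(f"{gene}\t{anchor}\t{rho}\t{fam}\t{dataset.truth.realized_r[gene]:.6f}\n")
    return paths
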