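"""Synthetic BXD-like cohorts with planted longevity-correlated genes.

The generator emulates the data landscape the screening pipeline targets:
a panel of isogenic strains with known median lifespans spanning a roughly
twofold range, and several tissue/sex expression datasets of which each
profiles only a partially overlapping subset of strains.

Background features are i.i.d. Gaussian noise, independent of lifespan.
A planted gene with signed target correlation rho is drawn from the
bivariate-normal construction

    expression(strain) = rho * z_L(strain) + sqrt(1 - rho^2) * eps,

where z_L is the standardized lifespan over the dataset's strain subset
and eps ~ N(0, 1) i.i.d., so rho is the exact population Pearson
correlation and parameter recovery is analytically checkable.

Randomness: the single config seed expands into independent per-purpose
streams via ``numpy.random.SeedSequence([seed, stream])`` — stream 0 for
lifespans, stream i+1 for dataset i — so adding a dataset never reshuffles
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OmicsDataset, to_two_z_plus_8

#: tissue/sex/omics roster cycled over datasets; the default eight entries
#: mirror a multi-tissue, sex-stratified design (two liver datasets are the
#: same tissue assayed at transcript and protein level).
DATASET_ROSTER = [
    ("adrenal", "male", "transcript"),
    ("adrenal", "female", "transcript"),
    ("kidney", "male", "transcript"),
    ("kidney", "female", "transcript"),
    ("liver", "female", "transcript"),
    ("liver", "female", "protein"),
    ("bone", "male", "transcript"),
    ("eye", "combined", "transcript"),
]


@dataclass(frozen=True)
class PlantedGene:
    """A gene with a planted lifespan correlation.

    ``rho`` maps dataset index -> signed target correlation; the gene is
    only measured in the listed datasets.
    """

    gene_id: str
    rho: dict

    def __post_init__(self):
        for i, value in self.rho.items():
            if not -1.0 <= value <= 1.0:
                raise ValueError(
                    f"planted rho for {self.gene_id} in dataset {i} "
                    f"outside [-1, 1]: {value}"
                )


def universal_planted(
    n_datasets: int, magnitude: float = 0.95
) -> list[PlantedGene]:
    """Two genes planted in every dataset with tissue-specific signs.

    The first carries positive correlations in the first half of the
    datasets and negative in the second; the second alternates sign.
    """
    half = n_datasets // 2
    return [
        PlantedGene(
            "LNG-A",
            {i: (magnitude if i < half else -magnitude) for i in range(n_datasets)},
        ),
        PlantedGene(
            "LNG-B",
            {i: (magnitude if i % 2 == 0 else -magnitude) for i in range(n_datasets)},
        ),
    ]


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the generator.

    Defaults describe a panel of 60 strains with median lifespans uniform
    on 450–900 days (a twofold spread), eight datasets of 43 strains each
    (partially overlapping subsets), 500 background features per dataset
    and two universal planted genes at |rho| = 0.95 with tissue-specific
    signs.
    """

    n_strains: int = 60
    lifespan_range: tuple = (450.0, 900.0)
    n_datasets: int = 8
    n_features_per_dataset: int = 500
    strains_per_dataset: int = 43
    planted: list = field(default_factory=list)
    noise_sd: float = 1.0
    normalization: str = "zscore"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.planted is None:
            self.planted = []
        if self.n_strains < 8:
            raise ValueError("n_strains must be >= 8")
        low, high = self.lifespan_range
        if not low < high:
            raise ValueError("lifespan_range must satisfy low < high")
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.strains_per_dataset > self.n_strains:
            raise ValueError("strains_per_dataset cannot exceed n_strains")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.normalization not in ("zscore", "two_z_plus_8"):
            raise ValueError("normalization must be zscore or two_z_plus_8")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def with_default_planted(cls, **kwargs) -> "SyntheticConfig":
        cfg = cls(**kwargs)
        if not cfg.planted:
            cfg.planted = universal_planted(cfg.n_datasets)
        return cfg

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        planted = [
            PlantedGene(p["gene_id"], {int(k): float(v) for k, v in p["rho"].items()})
            for p in d.pop("planted", [])
        ]
        use_default = d.pop("default_planted", not planted)
        if "lifespan_range" in d:
            d["lifespan_range"] = tuple(d["lifespan_range"])
        cfg = cls(planted=planted, **d)
        if use_default and not planted:
            cfg.planted = universal_planted(cfg.n_datasets)
        return cfg


@dataclass
class SyntheticTruth:
    """Ground truth of a generated panel: the recovery-test oracle.

    ``planted`` has one row per (dataset_id, gene_id) with the signed
    target correlation; ``strain_subsets`` maps dataset_id to the strain
    ids it profiles.
    """

    planted: pd.DataFrame
    lifespans: pd.DataFrame
    strain_subsets: dict

    def universal_genes(self, n_datasets: int) -> list[str]:
        """Genes planted in every dataset."""
        counts = self.planted.groupby("gene_id")["dataset_id"].nunique()
        return sorted(counts.index[counts == n_datasets])


def _stream(seed: int, stream: int) -> np.random.Generator:
    """Fixed seed-expansion rule: one independent stream per purpose."""
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def generate_lifespans(
    n_strains: int, lifespan_range=(450.0, 900.0), seed: int = 0
) -> pd.DataFrame:
    """Uniform strain median lifespans on ``lifespan_range`` (days)."""
    if n_strains < 2:
        raise ValueError("need at least 2 strains")
    low, high = lifespan_range
    if not low < high:
        raise ValueError("lifespan_range must satisfy low < high")
    rng = _stream(seed, 0)
    days = rng.uniform(low, high, size=n_strains)
    return pd.DataFrame(
        {
            "strain_id": [f"SYN{i + 1:03d}" for i in range(n_strains)],
            "median_lifespan_days": days,
            "sex": "combined",
        }
    )


def _dataset_metadata(index: int) -> tuple:
    tissue, sex, omics = DATASET_ROSTER[index % len(DATASET_ROSTER)]
    if index >= len(DATASET_ROSTER):
        tissue = f"{tissue}{index // len(DATASET_ROSTER) + 1}"
    dataset_id = f"d{index + 1}_{tissue}_{sex}_{omics}"
    return dataset_id, tissue, sex, omics


def generate_dataset(
    config: SyntheticConfig, lifespans: pd.DataFrame, dataset_index: int
) -> tuple:
    """One synthetic expression matrix plus its truth slice.

    Returns ``(OmicsDataset, truth_rows, strain_subset)``.
    """
    if not 0 <= dataset_index < config.n_datasets:
        raise ValueError("dataset_index out of range")
    rng = _stream(config.seed, dataset_index + 1)
    dataset_id, tissue, sex, omics = _dataset_metadata(dataset_index)

    strains = rng.choice(
        lifespans["strain_id"].to_numpy(),
        size=config.strains_per_dataset,
        replace=False,
    )
    strains = sorted(strains)
    life = (
        lifespans.set_index("strain_id")["median_lifespan_days"]
        .reindex(strains)
        .to_numpy(dtype=float)
    )
    z_life = (life - life.mean()) / life.std()
    m = len(strains)

    planted_here = [p for p in config.planted if dataset_index in p.rho]
    rows = []
    data = []
    truth_rows = []
    for p in planted_here:
        rho = p.rho[dataset_index]
        eps = rng.standard_normal(m)
        expr = rho * z_life + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps
        data.append(config.noise_sd * expr)
        rows.append(p.gene_id)
        truth_rows.append(
            {"dataset_id": dataset_id, "gene_id": p.gene_id, "rho": rho}
        )
    n_bg = config.n_features_per_dataset
    background = config.noise_sd * rng.standard_normal((n_bg, m))
    bg_ids = [f"BG{i + 1:05d}" for i in range(n_bg)]

    values = np.vstack([np.asarray(data).reshape(len(rows), m), background]) \
        if rows else background
    frame = pd.DataFrame(values, index=rows + bg_ids, columns=strains)

    if config.missing_rate > 0:
        mask = rng.random(frame.shape) < config.missing_rate
        frame = frame.mask(mask)

    if config.normalization == "two_z_plus_8":
        frame = to_two_z_plus_8(frame)

    dataset = OmicsDataset(
        dataset_id=dataset_id, tissue=tissue, sex=sex, omics_type=omics,
        normalization=config.normalization, values=frame,
    )
    return dataset, truth_rows, strains


def generate_panel(config: SyntheticConfig):
    """Generate the full panel.

    Returns ``(datasets, lifespans, truth)`` where ``datasets`` is a list
    of OmicsDataset and ``truth`` a :class:`SyntheticTruth`.
    """
    lifespans = generate_lifespans(
        config.n_strains, config.lifespan_range, config.seed
    )
    datasets = []
    truth_rows = []
    subsets = {}
    for i in range(config.n_datasets):
        dataset, rows, strains = generate_dataset(config, lifespans, i)
        datasets.append(dataset)
        truth_rows.extend(rows)
        subsets[dataset.dataset_id] = list(strains)
    planted = pd.DataFrame(truth_rows, columns=["dataset_id", "gene_id", "rho"])
    truth = SyntheticTruth(
        planted=planted, lifespans=lifespans, strain_subsets=subsets
    )
    return datasets, lifespans, truth


def identity_gene_map(datasets) -> dict:
    """Feature -> gene map for synthetic panels (features are genes)."""
    mapping = {}
    for ds in datasets:
        for f in ds.feature_ids:
            mapping[f] = f
    return mapping
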