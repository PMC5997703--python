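"""Synthetic datasets with known ground truth for the whole pipeline.

Emulates the study design of a serially sampled ancient mitogenome
survey: ~41 ancient individuals spanning roughly 14,000–1,400 BP split
into three temporal groups (means near 7,000 / 4,800 / 3,000 BP) and
three regional groups, plus a present-day comparative sample, all drawn
from one simulated population so that drift is the only source of
differentiation (the continuity null is true by construction).

Haplotypes come from the package's own serial coalescent under a known
demography; haplogroup-like labels are synthetic clade names cut from the
simulated genealogy (frequency/ordination machinery needs labels, not
PhyloTree nomenclature); isotope values are inert metadata drawn
uniformly from the aquatic-diet band typical of prehistoric fisher
populations (δ13C −22..−16‰, δ15N +10..+17‰).

Everything is a pure function of the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng

from .authenticity import BASES
from .coalsim import (
    GEN_TIME,
    MT_LENGTH,
    MU_MT,
    DemographicModel,
    Genealogy,
    SamplingSchedule,
    drop_mutations,
    simulate_genealogy,
)
from .exceptions import ModelError
from .io_meta import (
    METADATA_COLUMNS,
    HaplotypeAlignment,
    write_alignment,
    write_metadata,
)

_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"),
    "C": ("A", "G"),
    "G": ("C", "T"),
    "T": ("A", "G"),
}


def _default_demography() -> DemographicModel:
    # growth from 2,000 to 8,000 haploid females over the last 14,000 years
    # (560 generations): realistic regional female Ne, and a nucleotide
    # diversity giving haplotype diversity in the 0.95-1.0 band.
    return DemographicModel(
        n_recent=8000.0, n_anchor=2000.0, anchor_gen=560.0,
        mu=MU_MT, seq_len=MT_LENGTH, gen_time=GEN_TIME,
    )


@dataclass
class SyntheticScenario:
    """Study-design parameters for one synthetic dataset."""

    seed: int = 0
    n_early: int = 11
    n_middle: int = 16
    n_late: int = 11
    n_undated: int = 3  # ancients without a radiocarbon age / temporal bin
    n_modern: int = 20
    n_cisb: int = 23
    n_trab: int = 7
    n_yak: int = 9
    n_other: int = 2
    demography: DemographicModel = field(default_factory=_default_demography)
    contamination_frac: float = 0.10
    missing_rate: float = 0.002

    def __post_init__(self) -> None:
        counts = (
            self.n_early, self.n_middle, self.n_late, self.n_undated,
            self.n_modern, self.n_cisb, self.n_trab, self.n_yak, self.n_other,
        )
        if any(c < 0 for c in counts):
            raise ModelError("scenario counts must be non-negative")
        if self.n_ancient != self.n_cisb + self.n_trab + self.n_yak + self.n_other:
            raise ModelError(
                "spatial counts must partition the ancient samples: "
                f"{self.n_ancient} ancients vs "
                f"{self.n_cisb}+{self.n_trab}+{self.n_yak}+{self.n_other} spatial"
            )
        if not 0.0 <= self.contamination_frac <= 1.0:
            raise ModelError("contamination_frac must be in [0,1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ModelError("missing_rate must be in [0,1]")

    @property
    def n_ancient(self) -> int:
        return self.n_early + self.n_middle + self.n_late + self.n_undated


def _draw_ages(scenario: SyntheticScenario, rng: Generator) -> list[tuple[str, float]]:
    """Per-ancient (temporal label, age BP); Early/Middle/Late means near
    7,000/4,800/3,000 BP, full span anchored at ~13,790 and ~1,380 BP."""
    ages: list[tuple[str, float]] = []

    def draw(n: int, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
        a = np.clip(rng.normal(mean, sd, size=n), lo, hi)
        return np.round(a, 0)

    early = draw(scenario.n_early, 7000, 900, 5950, 13790)
    if scenario.n_early:
        early[0] = 13790.0  # a Palaeolithic outlier anchors the old end
    middle = draw(scenario.n_middle, 4800, 450, 3950, 5850)
    late = draw(scenario.n_late, 3000, 550, 1380, 3850)
    if scenario.n_late:
        late[-1] = 1380.0
    ages += [("Early", a) for a in early]
    ages += [("Middle", a) for a in middle]
    ages += [("Late", a) for a in late]
    # undated ancients: no age; simulated at a Middle-like age
    ages += [("", float("nan"))] * scenario.n_undated
    return ages


def _clade_labels(tree: Genealogy, rng: Generator, depth_fraction: float = 0.5) -> list[str]:
    """Synthetic haplogroup-like labels: clades cut at a fixed tree depth."""
    cut = depth_fraction * tree.tmrca()
    anc = np.arange(tree.n_nodes)
    labels = []
    for tip in range(tree.n_tips):
        node = tip
        while tree.parent[node] >= 0 and tree.time[tree.parent[node]] <= cut:
            node = tree.parent[node]
        labels.append(node)
    _, inv = np.unique(labels, return_inverse=True)
    return [f"HG{i+1:02d}" for i in inv]


def make_dataset(
    scenario: SyntheticScenario,
) -> tuple[HaplotypeAlignment, pd.DataFrame, Genealogy]:
    """Simulate one full dataset: alignment, metadata table, genealogy.

    All samples descend from a single population under the scenario
    demography; ancient tips enter the coalescent at their (rounded) ages.
    Missing data is injected as N at ``missing_rate`` per ancient cell.
    Byte-identical outputs are guaranteed for identical scenarios.
    """
    rng = default_rng(SeedSequence([scenario.seed, 0]))
    model = scenario.demography

    age_rows = _draw_ages(scenario, rng)
    undated_sim_age = 4800.0  # simulated age for undated ancients
    sample_rows: list[dict] = []
    sched_groups: list[tuple[str, int, float]] = []
    for i, (tlabel, age) in enumerate(age_rows):
        sid = f"syn{i+1:03d}"
        sim_age = undated_sim_age if np.isnan(age) else age
        sched_groups.append((sid, 1, sim_age))
        sample_rows.append(
            {"sample_id": sid, "temporal_group": tlabel if tlabel else np.nan,
             "age_bp": age}
        )
    for j in range(scenario.n_modern):
        sid = f"mod{j+1:03d}"
        sched_groups.append((sid, 1, 0.0))
        sample_rows.append(
            {"sample_id": sid, "temporal_group": "Modern", "age_bp": np.nan}
        )

    schedule = SamplingSchedule.from_ages_bp(
        sched_groups, gen_time=model.gen_time, reference_bp=0.0
    )
    tree = simulate_genealogy(model, schedule, rng)
    aln = drop_mutations(tree, model.mu, model.seq_len, rng)
    aln = HaplotypeAlignment(
        [r["sample_id"] for r in sample_rows], aln.matrix, aln.coord_offset
    )

    # spatial labels and sites over the ancients
    spatial = (
        ["CISB"] * scenario.n_cisb + ["TRAB"] * scenario.n_trab
        + ["YAK"] * scenario.n_yak + ["OTHER"] * scenario.n_other
    )
    spatial = list(rng.permutation(spatial))
    site_pool = {
        "CISB": [f"CISB_site{i+1}" for i in range(4)],
        "TRAB": [f"TRAB_site{i+1}" for i in range(2)],
        "YAK": [f"YAK_site{i+1}" for i in range(3)],
        "OTHER": ["Krasnoyarsk", "Blagoveshchensk"],
    }
    haplogroups = _clade_labels(tree, rng)
    for i, row in enumerate(sample_rows):
        row["haplogroup"] = haplogroups[i]
        if row["temporal_group"] == "Modern":
            row["spatial_group"] = "OTHER"
            row["site"] = "present-day"
            row["d13C"] = np.nan
            row["d15N"] = np.nan
        else:
            sp = spatial[i]
            row["spatial_group"] = sp
            row["site"] = site_pool[sp][rng.integers(0, len(site_pool[sp]))]
            row["d13C"] = round(float(rng.uniform(-22.0, -16.0)), 2)
            row["d15N"] = round(float(rng.uniform(10.0, 17.0)), 2)
    meta = pd.DataFrame(sample_rows)[METADATA_COLUMNS]

    if scenario.missing_rate > 0:
        n_anc = scenario.n_ancient
        mask = rng.random((n_anc, aln.length)) < scenario.missing_rate
        aln.matrix[:n_anc][mask] = ord("N")
    return aln, meta, tree


def make_qc_fixtures(
    scenario: SyntheticScenario,
    n_informative: int = 60,
    mean_depth: float = 80.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pileup and sex-count fixtures with known ground truth.

    Informative pileup rows are panel-rare consensus sites whose
    alternative base is a transversion partner carrying reads at the
    scenario's contamination fraction.  Decoy rows exercise every filter:
    panel-common sites, shallow sites, and deamination-like transition
    sites with inflated alternative counts.  Sex counts contain known
    females (Ry ~ 0.002 mismapping noise) and known males (Ry ~ 0.1).
    """
    rng = default_rng(SeedSequence([scenario.seed, 1]))
    c = scenario.contamination_frac
    rows = []
    pos = 1

    def add_site(consensus: str, alt: str, alt_p: float, depth: int, panel: float):
        nonlocal pos
        # the consensus must stay the majority base at every site
        n_alt = min(int(rng.binomial(depth, alt_p)), depth // 2)
        counts = {b: 0 for b in BASES}
        counts[consensus] = depth - n_alt
        counts[alt] = n_alt
        rows.append(
            {"position": pos, **counts, "consensus_base": consensus,
             "panel_freq": round(panel, 4)}
        )
        pos += rng.integers(50, 400)

    bases = list(BASES)
    for _ in range(n_informative):
        cons = bases[rng.integers(0, 4)]
        alt = _TRANSVERSION_PARTNERS[cons][rng.integers(0, 2)]
        depth = int(rng.poisson(mean_depth)) + 10
        add_site(cons, alt, c, depth, float(rng.uniform(0.0, 0.04)))
    for _ in range(10):  # panel-common: filtered out
        cons = bases[rng.integers(0, 4)]
        alt = _TRANSVERSION_PARTNERS[cons][rng.integers(0, 2)]
        add_site(cons, alt, 0.5, int(rng.poisson(mean_depth)) + 10,
                 float(rng.uniform(0.2, 0.99)))
    for _ in range(5):  # too shallow: filtered out
        cons = bases[rng.integers(0, 4)]
        alt = _TRANSVERSION_PARTNERS[cons][rng.integers(0, 2)]
        add_site(cons, alt, 0.5, int(rng.integers(1, 9)), float(rng.uniform(0.0, 0.04)))
    transitions = {"C": "T", "T": "C", "G": "A", "A": "G"}
    for _ in range(10):
        # deamination-like transition sites; kept panel-common so they are
        # fully filtered — a panel-rare transition-only site would dilute
        # the pooled estimate (its consensus reads count, its alternatives
        # are zeroed) and break exact parameter recovery
        cons = bases[rng.integers(0, 4)]
        add_site(cons, transitions[cons], 0.2, int(rng.poisson(mean_depth)) + 10,
                 float(rng.uniform(0.2, 0.99)))
    pileups = pd.DataFrame(rows)

    sex_rows = []
    for i in range(7):
        n = int(rng.integers(3000, 8000))
        sex_rows.append(
            {"sample_id": f"female{i+1:02d}", "true_sex": "female",
             "n_y": int(rng.binomial(n, 0.002)), "n_x": 0}
        )
        sex_rows[-1]["n_x"] = n - sex_rows[-1]["n_y"]
    for i in range(7):
        n = int(rng.integers(3000, 8000))
        n_y = int(rng.binomial(n, 0.10))
        sex_rows.append(
            {"sample_id": f"male{i+1:02d}", "true_sex": "male",
             "n_y": n_y, "n_x": n - n_y}
        )
    sex = pd.DataFrame(sex_rows)[["sample_id", "n_y", "n_x", "true_sex"]]
    return pileups, sex


def write_dataset(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write alignment FASTA, metadata TSV and QC fixture TSVs to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln, meta, tree = make_dataset(scenario)
    pileups, sex = make_qc_fixtures(scenario)
    paths = {
        "alignment": out / "alignment.fasta",
        "metadata": out / "metadata.tsv",
        "pileups": out / "pileups.tsv",
        "sex_counts": out / "sex_counts.tsv",
        "tree": out / "genealogy.nwk",
    }
    write_alignment(aln, paths["alignment"])
    write_metadata(meta, paths["metadata"])
    pileups.to_csv(paths["pileups"], sep="\t", index=False)
    sex.to_csv(paths["sex_counts"], sep="\t", index=False)
    paths["tree"].write_text(tree.to_newick() + "\n")
    return paths
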