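"""Shared fixtures: tiny on-disk datasets and a planted-module study.

Everything is generated programmatically; seed 7 throughout so runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from comethyl import conetwork, differential, methylation_values, synthetic_data
from comethyl.core_io import ProbeAnnotation, SampleSheet

SEED = 7


@pytest.fixture()
def small_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {"group": ["case", "case", "control", "control"]},
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )


@pytest.fixture()
def small_annotation() -> ProbeAnnotation:
    probes = [f"cg{i:06d}" for i in range(1, 5)]
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": "chr1",
                "position": [100, 200, 300, 400],
                "promoter_id": ["P1", "P1", "P2", None],
                "gene_id": ["G1", "G1", "G2", None],
                "tiling_id": ["T1", "T1", "T1", "T2"],
                "cpg_island_id": [None, None, "I1", None],
                "promoter_annotated": [True, True, True, False],
            },
            index=pd.Index(probes, name="probe_id"),
        )
    )


@pytest.fixture()
def dataset_files(tmp_path, small_annotation):
    """Write a 4-probe × 4-sample β dataset to disk; returns the three paths."""
    sheet_path = tmp_path / "sheet.csv"
    sheet_path.write_text(
        "sample_id,group\ns1,hypersensitive\ns2,case\ns3,tolerant\ns4,control\n"
    )
    rng = np.random.default_rng(SEED)
    beta = pd.DataFrame(
        rng.uniform(0.1, 0.9, size=(4, 4)),
        index=pd.Index([f"cg{i:06d}" for i in range(1, 5)], name="probe_id"),
        columns=["s1", "s2", "s3", "s4"],
    )
    matrix_path = tmp_path / "beta.tsv"
    beta.to_csv(matrix_path, sep="\t")
    annotation_path = tmp_path / "annotation.tsv"
    small_annotation.data.to_csv(annotation_path, sep="\t", index_label="probe_id", na_rep="NA")
    return sheet_path, matrix_path, annotation_path


@dataclass
class PlantedStudy:
    """A planted-module cohort pushed through the full analysis path."""

    config: synthetic_data.SimulationConfig
    sheet: SampleSheet
    annotation: ProbeAnnotation
    truth: synthetic_data.GroundTruth
    regions: differential.RegionMatrix
    region_stats: pd.DataFrame
    gs: pd.Series
    net: conetwork.CoMethylationNetwork


@pytest.fixture(scope="session")
def planted_study() -> PlantedStudy:
    """Three 60-promoter modules + 120 null promoters, 15 vs 20 samples,
    loadings in [0.7, 0.9], noise sd 0.2 — analyzed at soft power 14."""
    config = synthetic_data.SimulationConfig(
        seed=SEED,
        n_promoters=300,
        n_modules=3,
        module_sizes=(60, 60, 60),
        loading_range=(0.7, 0.9),
        noise_sd=0.2,
    )
    sheet, intensities, annotation, truth = synthetic_data.simulate_dataset(config)
    beta = methylation_values.compute_beta(intensities)
    m = methylation_values.beta_to_m(beta)
    regions = differential.summarize_regions(m, annotation, "promoter")
    stats = differential.test_features(regions.as_methylation_matrix(), sheet)
    gs = pd.Series(
        conetwork.gene_significance(stats["p_value"]), index=stats.index, name="GS"
    )
    net = conetwork.CoMethylationNetwork(power=14).fit(regions.values.T)
    return PlantedStudy(config, sheet, annotation, truth, regions, stats, gs, net)
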