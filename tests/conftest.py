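import pytest

from pepdisplay import (
    LibraryDesign,
    SimulationConfig,
    SpecificityModel,
    process_sample,
    simulate_screen,
)


@pytest.fixture(scope="session")
def x5_design():
    return LibraryDesign.x5_y_x5()


@pytest.fixture(scope="session")
def scanning_design():
    return LibraryDesign.src_consensus_scanning()


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory, x5_design):
    """A small degenerate screen (zero sequencing error) shared across
    tests: simulated FASTQ pair plus processed records."""
    out = tmp_path_factory.mktemp("small_screen")
    labels = x5_design.position_labels()
    model = SpecificityModel.from_preferences(
        11, {(-2, "I"): 1.2, (1, "E"): 0.9}, positions=labels, baseline_rate=0.2
    )
    config = SimulationConfig(
        design=x5_design, n_cells=4000, reads_per_sample=4000, seed=11
    )
    result = simulate_screen(config, model, out)
    recs_sorted, stats_sorted = process_sample(
        result["sorted_files"]["r1"], result["sorted_files"]["r2"], x5_design, sample_id="s"
    )
    recs_unsorted, stats_unsorted = process_sample(
        result["unsorted_files"]["r1"], result["unsorted_files"]["r2"], x5_design, sample_id="u"
    )
    return {
        "design": x5_design,
        "model": model,
        "config": config,
        "result": result,
        "records_sorted": recs_sorted,
        "records_unsorted": recs_unsorted,
        "stats_sorted": stats_sorted,
        "stats_unsorted": stats_unsorted,
    }
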