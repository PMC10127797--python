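import pytest
from hypothesis import HealthCheck, settings

from lrpmap import sim, tracks

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config():
    """Study-condition generator config: 500 kb circular replicon, 40 primary
    sites, satellites at 1.2-2.0 kb, SNR 5."""
    return sim.SimConfig(seed=11)


@pytest.fixture(scope="session")
def experiment(config):
    tss, tus, truth = sim.simulate_experiment(config)
    return tss, tus, truth


@pytest.fixture(scope="session")
def scar_reference(config, experiment):
    """Averaged scar rz track per medium (Log phase, lineage 1)."""
    _, _, truth = experiment
    out = {}
    for medium in ("Min", "LIV"):
        rzs = []
        for biorep in (1, 2):
            meta = tracks.SampleMeta("scar", medium, "Log", 1, biorep)
            chip, inp = sim.simulate_chip_tracks(config, truth, meta)
            rzs.append(tracks.score_track(chip, inp))
        out[medium] = list(tracks.average_replicates(rzs).values())[0]
    return out


@pytest.fixture(scope="session")
def averaged_subtracted(config, experiment):
    """Replicate-averaged scar-subtracted occupancy per (genotype, medium),
    pooling 2 lineages x 2 bioreps as in the study design."""
    _, _, truth = experiment

    def averaged_rz(genotype, medium):
        rzs = []
        for lineage in (1, 2):
            for biorep in (1, 2):
                meta = tracks.SampleMeta(genotype, medium, "Log", lineage, biorep)
                chip, inp = sim.simulate_chip_tracks(config, truth, meta)
                rzs.append(tracks.score_track(chip, inp))
        (avg,) = tracks.average_replicates(rzs, group_by=("genotype", "medium")).values()
        return avg

    out = {}
    for medium in ("Min", "LIV"):
        scar = averaged_rz("scar", medium)
        for genotype in ("WT", "D114E", "L136R"):
            out[(genotype, medium)] = tracks.subtract_scar(
                averaged_rz(genotype, medium), scar
            )
    return out


@pytest.fixture(scope="session")
def wt_min_subtracted(config, experiment, scar_reference):
    """Scar-subtracted WT occupancy in minimal medium (one replicate)."""
    _, _, truth = experiment
    meta = tracks.SampleMeta("WT", "Min", "Log", 1, 1)
    chip, inp = sim.simulate_chip_tracks(config, truth, meta)
    rz = tracks.score_track(chip, inp)
    return tracks.subtract_scar(rz, scar_reference["Min"])
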