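import pytest

from survmeta.data import Dataset, KMPoint, StudyArm
from survmeta.hazards import (
    CovariateModel,
    CovariateTerm,
    HazardModelSpec,
    survival,
)
from survmeta.nlme import PopulationParams
from survmeta.simulate import GeneratorConfig, generate_survival_dataset


def make_arm(arm_id="A1", study_id="S1", regimen="G", n=100, age=72.5,
             ps2=14.0, **kw):
    defaults = dict(male_pct=80.0, stage4_pct=79.0, scc_pct=34.0,
                    adc_pct=41.1, lcc_pct=9.8)
    defaults.update(kw)
    return StudyArm(study_id=study_id, arm_id=arm_id, regimen=regimen, n=n,
                    age_median=age, ps2_pct=ps2, **defaults)


def noiseless_curve(beta0, times, se=0.02):
    spec = HazardModelSpec("constant", beta0)
    return tuple(KMPoint(float(t), float(survival(spec, t)), se) for t in times)


@pytest.fixture
def published_params():
    """Final-model parameters as printed: beta0 0.098, age/PS2 coefficients."""
    return PopulationParams(
        spec=HazardModelSpec("constant", 0.098),
        cov_model=CovariateModel(
            (CovariateTerm("age", 0.017, 72.5),
             CovariateTerm("ps2_pct", 0.004, 14.0))
        ),
        omega2=0.146**2,
        sigma_eps=0.822,
    )


@pytest.fixture
def two_arm_dataset():
    """Tiny deterministic dataset: two arms with exact exponential curves."""
    arms = (make_arm("A1", "S1", "GV", n=100, age=62.0, ps2=12.0),
            make_arm("A2", "S2", "G", n=50, age=75.0, ps2=35.0))
    times = [3.0, 6.0, 12.0, 24.0]
    curves = {"A1": noiseless_curve(0.08, times),
              "A2": noiseless_curve(0.12, times)}
    return Dataset(arms, curves)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """One paper-scale synthetic dataset (17 studies / 20 arms) plus truth."""
    return generate_survival_dataset(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def paper_scale_fit(paper_scale_dataset):
    from survmeta.nlme import fit_model

    dataset, truth = paper_scale_dataset
    return fit_model(dataset, family="constant",
                     covariate_terms=("age", "ps2_pct"),
                     covariate_refs={"age": 72.5, "ps2_pct": 14.0})
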