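import pytest

from prioritizer.pipeline import RunConfig, run_all
from prioritizer.synthetic_data import CallerProfile, CohortSpec, generate_cohort


def make_run_config(paths, **overrides) -> RunConfig:
    kwargs = dict(
        vcf_dir=str(paths.vcf_dir),
        counts=str(paths.counts),
        annotations=str(paths.annotations),
        expressed_genes=str(paths.expressed_genes),
        seg=str(paths.seg),
        bed=str(paths.bed),
        external_counts=str(paths.external_counts),
        census=str(paths.census),
        gene_sets=str(paths.gene_sets),
        capture_counts=str(paths.capture_counts),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def nonoise_spec(seed: int = 7, **overrides) -> CohortSpec:
    """Perfect callers and predictors: pipeline output is exactly derivable."""
    defaults = dict(
        seed=seed,
        caller_profiles={
            c: CallerProfile(1.0, 0) for c in ("bcftools", "varscan", "freebayes")
        },
        predictor_concordance=1.0,
        predictor_missing_rate=0.0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def nonoise_cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("nonoise_cohort")
    spec = nonoise_spec()
    paths, truth = generate_cohort(spec, outdir)
    return spec, paths, truth


@pytest.fixture(scope="session")
def nonoise_report(nonoise_cohort, tmp_path_factory):
    _, paths, _ = nonoise_cohort
    out = tmp_path_factory.mktemp("nonoise_out")
    report = run_all(make_run_config(paths), out)
    return report, out


@pytest.fixture(scope="session")
def noisy_cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("noisy_cohort")
    spec = CohortSpec(seed=11)  # default caller error model
    paths, truth = generate_cohort(spec, outdir)
    return spec, paths, truth
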