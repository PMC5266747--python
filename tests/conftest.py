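import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The AGP-like sequence of AtAGP1 (82 residues): the canonical worked
# example fixing the greedy non-overlapping counting convention.
ATAGP1_AGP_LIKE = (
    "SPAPAPSNVGGRRISPAPSPKKMTAPAPAPEVSPSPSPAAAL"
    "TPESSASPPSPPLADSPTADSPALSPSAISDSPTEAPGPA"
)


@pytest.fixture
def atagp1():
    return ATAGP1_AGP_LIKE


@pytest.fixture(scope="session")
def small_proteome():
    """A small planted proteome shared by screening/synthetic tests."""
    from finding_agp.synthetic import SynthConfig, generate_proteome

    config = SynthConfig(
        seed=7,
        n_classical=4, n_pep=3, n_kc=2, n_hae=2, n_fla=2, n_pag=2, n_xylp=2,
        n_other_chimeric=1, n_ext=2, n_prp=2, n_neg_gap=3, n_neg_sparse=3,
        n_neg_lowpast=3, n_background=60,
    )
    return generate_proteome(config)


def blast_hits_from_rows(rows):
    from finding_agp.seqio import BlastHit

    return [BlastHit(r[0], r[1], float(r[10])) for r in rows]
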