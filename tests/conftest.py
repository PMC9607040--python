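import itertools

import pytest

from peristream import FlowParameters, Variant

#: parameter grid spanning the figure-caption values (wave number,
#: Reynolds number, compressibility, relaxation time)
GRID_ALPHA = (0.1, 0.5, 1.0)
GRID_REYNOLDS = (10.0, 100.0, 1.0e4)
GRID_CHI = (0.001, 0.3, 0.6)
GRID_LAMBDA1 = (0.0, 0.5, 5.0)


def caption_grid(variant=Variant.UCM):
    return [
        FlowParameters(alpha=a, reynolds=R, chi=chi, lambda1=l1, variant=variant)
        for a, R, chi, l1 in itertools.product(
            GRID_ALPHA, GRID_REYNOLDS, GRID_CHI, GRID_LAMBDA1
        )
    ]


def oracle_tol(params):
    """Collocation mesh tolerance: relaxed in the stiff boundary-layer
    regimes where refinement is oscillation-limited."""
    from peristream import derive_mode_constants

    c = derive_mode_constants(params)
    kmax = max(abs(c.beta), abs(c.nu))
    return 1e-9 if kmax <= 50 else 1e-6


@pytest.fixture(scope="session")
def rep_params():
    """Representative parameter point used throughout the study."""
    return FlowParameters(alpha=0.5, reynolds=10.0, chi=0.3, lambda1=0.5,
                          variant=Variant.UCM)


@pytest.fixture(scope="session")
def rep_first_order(rep_params):
    from peristream import solve_first_order

    return solve_first_order(rep_params)


@pytest.fixture(scope="session")
def rep_second_order(rep_params):
    from peristream import solve_second_order

    return solve_second_order(rep_params)
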