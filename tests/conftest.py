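import pytest

from etcc.carrying_capacity import compute_site
from etcc.datasets import (
    TEHRAN_CF7_PERCENT,
    TEHRAN_RCC_DAILY,
    load_tehran_dataset,
    load_tehran_delphi_round3,
)


@pytest.fixture(scope="session")
def tehran():
    """The bundled three-site dataset: (sites, zones, climate, management)."""
    return load_tehran_dataset()


@pytest.fixture(scope="session")
def tehran_by_site(tehran):
    sites, zones, climate, management = tehran
    return {
        "sites": {s.name: s for s in sites},
        "zones": zones,
        "climate": {c.site_name: c for c in climate},
        "management": {m.site_name: m for m in management},
    }


@pytest.fixture(scope="session")
def tehran_results(tehran_by_site):
    """Full cascade over the bundled dataset, keyed by (site, use, class)."""
    results = {}
    for name, profile in tehran_by_site["sites"].items():
        for res in compute_site(
            profile,
            tehran_by_site["zones"],
            tehran_by_site["climate"][name],
            tehran_by_site["management"][name],
            cf_percent_overrides=TEHRAN_CF7_PERCENT[name],
            rcc_injection=TEHRAN_RCC_DAILY,
        ):
            results[res.zone_key] = res
    return results


@pytest.fixture(scope="session")
def tehran_delphi():
    return load_tehran_delphi_round3()
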