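import pytest

from pvsignal.cohort_summary import cohort_from_counts
from pvsignal.disproportionality import ContingencyTable
from pvsignal.synthetic_faers import SimConfig, generate, write_corpus

# Desk-check cohort: the marginal counts of an observed mogamulizumab
# reporting cohort (1182 deduplicated primary-suspect reports; 1012 of them
# carry a serious-outcome classification).
TABLE1_COUNTS = {
    "year_counts": {"2018": 19, "2019": 209, "2020": 193, "2021": 254,
                    "2022": 326, "2023": 181},
    "reporter_counts": {"Pharmacist": 722, "Physician": 240,
                        "Other health-professional": 161, "Consumer": 58,
                        "Unknown": 1},
    "country_counts": {"United States": 694, "Japan": 211, "France": 98,
                       "Germany": 60, "Italy": 60, "Canada": 59},
    "outcome_counts": {"Hospitalization": 225, "Death": 197,
                       "Life threatening": 35, "Disability": 9,
                       "Other serious": 546},
    "n_no_outcome": 170,
}


@pytest.fixture(scope="session")
def table1_cohort():
    return cohort_from_counts(**TABLE1_COUNTS)


@pytest.fixture
def toy_table():
    """The worked 2x2 example used throughout: a=5, b=10, c=20, d=100."""
    return ContingencyTable(5, 10, 20, 100)


PLANTED = (("mogamulizumab", "Event 007", 10.0),
           ("mogamulizumab", "Event 120", 10.0))


@pytest.fixture(scope="session")
def sim_corpus():
    """A seeded synthetic corpus with two planted signals (in memory)."""
    config = SimConfig(seed=7, planted_signals=PLANTED)
    tables, truth = generate(config)
    return config, tables, truth


@pytest.fixture(scope="session")
def sim_corpus_dir(sim_corpus, tmp_path_factory):
    """The same corpus written out as quarterly FAERS files."""
    _, tables, truth = sim_corpus
    directory = tmp_path_factory.mktemp("corpus")
    write_corpus(tables, truth, directory)
    return directory
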