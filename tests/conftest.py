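import pandas as pd
import pytest

from aurumkit import StudyRecipe, connect, cprd_extract, generate_fixture, generate_study


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    """The 12-patient worked-example file tree (patients 1-8 in set 1 with
    three observation and three drug-issue parts; patients 9-12 in set 2)."""
    root = tmp_path_factory.mktemp("fixture")
    manifest = generate_fixture(root, seed=1)
    return root, manifest


@pytest.fixture(scope="session")
def study_tree(tmp_path_factory):
    """A small randomized study: 300 patients over 2 sets, code H1 planted
    pre-index with probability 0.2."""
    root = tmp_path_factory.mktemp("study")
    recipe = StudyRecipe(
        n_patients=300, obs_per_patient=20, code_prevalences={"H1": 0.2}, seed=11
    )
    manifest = generate_study(recipe, root)
    return root, recipe, manifest


@pytest.fixture(scope="session")
def study_store(study_tree, tmp_path_factory):
    """The study tree ingested into a store (observation + drugissue)."""
    root, recipe, _ = study_tree
    db = tmp_path_factory.mktemp("db") / "study.sqlite"
    handle = connect(db)
    cprd_extract(handle, root, "observation")
    cprd_extract(handle, root, "drugissue")
    yield root, recipe, handle
    handle.close()


@pytest.fixture()
def make_store(tmp_path):
    """Build a store directly from in-memory observation (and optionally
    drug-issue) rows, for unit-testing the extraction rules in isolation.
    Dates are ISO strings, as the ingest path stores them."""
    handles = []

    def _make(observation_rows, drugissue_rows=None):
        path = tmp_path / f"unit{len(handles)}.sqlite"
        handle = connect(path)
        obs = pd.DataFrame(
            observation_rows,
            columns=["patid", "medcodeid", "obsdate", "value", "numunitid"],
        )
        obs.to_sql("observation", handle.conn, index=False)
        if drugissue_rows is not None:
            drug = pd.DataFrame(
                drugissue_rows, columns=["patid", "prodcodeid", "issuedate"]
            )
            drug.to_sql("drugissue", handle.conn, index=False)
        handles.append(handle)
        return handle

    yield _make
    for h in handles:
        h.close()


@pytest.fixture()
def simple_cohort():
    """Two-patient cohort with a fixed index date and one year follow-up."""
    return pd.DataFrame(
        {
            "patid": ["1", "2"],
            "indexdt": pd.to_datetime(["2010-01-01", "2010-01-01"]),
            "censdt": pd.to_datetime(["2010-12-31", "2010-12-31"]),
        }
    )
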