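import pytest

from trinorm import demo_rules, pipeline, synthetic


@pytest.fixture(scope="session")
def age_demo():
    return demo_rules.demo_rulesets("age")


@pytest.fixture(scope="session")
def dataloc_demo():
    return demo_rules.demo_rulesets("data_loc")


def make_workspace(tmp_path, dataset, demo, corpus, **config_kwargs):
    """Write demo rules, config and a corpus into a pipeline workdir."""
    from trinorm.rule_store import save_phrase_ruleset
    from trinorm.synthetic import write_items_tsv

    workdir = tmp_path / dataset
    workdir.mkdir(parents=True, exist_ok=True)
    input_path = workdir / f"{dataset}_input.tsv"
    write_items_tsv([messy for messy, _ in corpus], input_path)
    config = pipeline.PipelineConfig(
        dataset_name=dataset,
        input_path=str(input_path),
        workdir=str(workdir),
        protected_prefixes=list(demo["protected_prefixes"]),
        enable_splitter=demo["enable_splitter"],
        enable_pdb_autocategory=demo["enable_pdb_autocategory"],
        mass_allow=[list(p) for p in demo["mass_allow"]],
        **config_kwargs,
    )
    demo["char_reference"].to_tsv(config.file("char_reference"))
    demo["word_reference"].to_tsv(config.file("word_reference"))
    save_phrase_ruleset(demo["phrase_ruleset"], config.file("phrase_types"))
    return config


@pytest.fixture
def age_workspace(tmp_path, age_demo):
    corpus = synthetic.generate_age_corpus(synthetic.FixtureSpec(n_items=60, seed=11))
    return make_workspace(tmp_path, "age", age_demo, corpus), corpus


@pytest.fixture
def dataloc_workspace(tmp_path, dataloc_demo):
    corpus = synthetic.generate_dataloc_corpus(
        synthetic.FixtureSpec(n_items=60, seed=11)
    )
    return make_workspace(tmp_path, "data_loc", dataloc_demo, corpus), corpus
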