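import numpy as np
import pytest

import varprio as vp


@pytest.fixture(scope="session")
def paper_fixture():
    """The packaged worked example: 10 FLNA variants, 9 clinical records."""
    return vp.make_paper_fixture()


@pytest.fixture(scope="session")
def paper_verdicts(paper_fixture):
    variants, _ = paper_fixture
    return vp.classify_all(variants, hi_table=vp.PAPER_HI_TABLE)


def random_variant(rng: np.random.Generator, **overrides) -> vp.AnnotatedVariant:
    """A random well-formed variant touching every gate and route."""
    classes = list(vp.VariantClass)
    vc = overrides.pop("variant_class", classes[rng.integers(len(classes))])
    calls = {}
    for tool in vp.PREDICTOR_TOOLS:
        r = rng.random()
        if r < 0.2:
            continue  # missing
        rule = vp.DEFAULT_REGISTRY[tool]
        if rule.mode == "categorical":
            calls[tool] = str(
                rng.choice(sorted(rule.damaging_categories) + ["T", "B", "N"])
            )
        else:
            calls[tool] = float(rng.uniform(0, rule.threshold * 2))
    kwargs = dict(
        sample_id="Patient1-P",
        patient_id="Patient1",
        tumor_group=vp.TumorGroup.primary,
        chrom=str(rng.integers(1, 23)),
        start=int(rng.integers(1, 10**8)),
        end=0,
        ref="A",
        alt="T",
        gene=f"G{rng.integers(50)}",
        variant_class=vc,
        depth=int(rng.integers(0, 60)),
        exac_eas_freq=None if rng.random() < 0.4 else float(rng.uniform(0, 0.05)),
        predictor_calls=calls,
        vest_indel_score=None if rng.random() < 0.3 else float(rng.random()),
        vest_indel_p=None if rng.random() < 0.3 else float(rng.random()),
    )
    kwargs.update(overrides)
    kwargs["end"] = max(kwargs["end"], kwargs["start"])
    return vp.AnnotatedVariant(**kwargs)
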