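import random

import pytest

import clinspell as cs


@pytest.fixture(scope="session")
def tables():
    return cs.ConjugationTables()


@pytest.fixture(scope="session")
def worked_example_lexicon():
    """Lexicon attesting the error forms of the documented rule examples."""
    words = {
        "unido", "unida", "traicioneras", "traicioneros",
        "aeronave", "aeronaves", "virtudes", "virtud",
        "sinuosos", "sinuosa", "abandonado", "abandonadas",
        "a", "ha", "enebro", "enhebro", "uso", "huso",
        "calle", "callé", "agravio", "agrado", "masa", "amas",
        "llevar", "llevan", "llevas", "pelear", "peleaba", "peleábamos",
        "hemos", "mesa",
    }
    return cs.Lexicon({w: 5 for w in words})


@pytest.fixture(scope="session")
def synth_corpus():
    return cs.generate_corpus(1500, 11)


@pytest.fixture(scope="session")
def synth_lexicon(synth_corpus):
    return cs.mini_lexicon(synth_corpus)


@pytest.fixture(scope="session")
def synth_groups(synth_lexicon):
    return cs.build_rule_groups(synth_lexicon)


@pytest.fixture(scope="session")
def skip_list():
    return cs.load_skip_list()


@pytest.fixture()
def rng():
    return random.Random(1234)


def indel_bruteforce(a: str, b: str, memo: dict | None = None) -> int:
    """Independent oracle: exhaustive search over insert/delete edit
    scripts (memoized recursion on string suffixes; no LCS formula)."""
    if memo is None:
        memo = {}
    key = (a, b)
    if key in memo:
        return memo[key]
    if not a:
        r = len(b)
    elif not b:
        r = len(a)
    elif a[0] == b[0]:
        r = indel_bruteforce(a[1:], b[1:], memo)
    else:
        r = 1 + min(
            indel_bruteforce(a[1:], b, memo),
            indel_bruteforce(a, b[1:], memo),
        )
    memo[key] = r
    return r
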