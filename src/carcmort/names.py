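"""Name generation and corruption for the synthetic registries.

Names are drawn from small frequency-weighted pools of common Brazilian
given names and surnames (ASCII-folded, upper case, as administrative
databases typically store them). A mother's name shares a surname with her
child with probability ``SHARED_SURNAME_PROB``, which creates the realistic
ambiguity the deduplication decision trees have to resolve.
"""

from __future__ import annotations

import numpy as np

from .config import NameNoise

MALE_GIVEN = [
    "JOSE", "JOAO", "ANTONIO", "FRANCISCO", "CARLOS", "PAULO", "PEDRO",
    "LUCAS", "LUIZ", "MARCOS", "LUIS", "GABRIEL", "RAFAEL", "DANIEL",
    "MARCELO", "BRUNO", "EDUARDO", "FELIPE", "RODRIGO", "MANOEL",
    "MATEUS", "ANDRE", "FERNANDO", "FABIO", "LEONARDO", "GUSTAVO",
    "GUILHERME", "LEANDRO", "TIAGO", "RICARDO", "ALEXANDRE", "DIEGO",
    "VINICIUS", "JORGE", "ROBERTO", "SERGIO", "ADRIANO", "CLAUDIO",
    "ANDERSON", "THIAGO", "WELLINGTON", "JEFERSON", "MAURICIO", "ALEX",
    "VITOR", "RENATO", "IGOR", "CAIO", "JULIO", "CESAR", "OTAVIO",
    "WAGNER", "EVERTON", "JAIR", "NELSON", "OSVALDO", "RAIMUNDO",
    "SEBASTIAO", "VALDIR", "GERALDO",
]
FEMALE_GIVEN = [
    "MARIA", "ANA", "FRANCISCA", "ANTONIA", "ADRIANA", "JULIANA",
    "MARCIA", "FERNANDA", "PATRICIA", "ALINE", "SANDRA", "CAMILA",
    "AMANDA", "BRUNA", "JESSICA", "LETICIA", "JULIA", "LUCIANA",
    "VANESSA", "MARIANA", "GABRIELA", "VERA", "VITORIA", "LARISSA",
    "CLAUDIA", "BEATRIZ", "LUZIA", "RITA", "SONIA", "RENATA",
    "APARECIDA", "FATIMA", "JOANA", "TEREZA", "ROSANGELA", "CRISTINA",
    "SIMONE", "ELIANE", "ROSA", "HELENA", "MARLENE", "REGINA",
    "IVONE", "NEUSA", "CELIA", "IRACEMA", "DALVA", "ZILDA",
]
SURNAMES = [
    "SILVA", "SANTOS", "OLIVEIRA", "SOUZA", "RODRIGUES", "FERREIRA",
    "ALVES", "PEREIRA", "LIMA", "GOMES", "COSTA", "RIBEIRO", "MARTINS",
    "CARVALHO", "ALMEIDA", "LOPES", "SOARES", "FERNANDES", "VIEIRA",
    "BARBOSA", "ROCHA", "DIAS", "NASCIMENTO", "ANDRADE", "MOREIRA",
    "NUNES", "MARQUES", "MACHADO", "MENDES", "FREITAS", "CARDOSO",
    "RAMOS", "GONCALVES", "SANTANA", "TEIXEIRA", "ARAUJO", "MELO",
    "CASTRO", "CAMPOS", "MORAES", "CORREIA", "BATISTA", "BORGES",
    "MONTEIRO", "DUARTE", "CAVALCANTE", "MIRANDA", "REIS", "PINTO",
    "FARIAS", "AZEVEDO", "CUNHA", "GUIMARAES", "TAVARES", "XAVIER",
    "ESPINDOLA", "ORTIZ", "AQUINO", "BRITO", "MEDEIROS",
]

# connectives common in Brazilian full names, inserted between surnames
CONNECTIVES = ["DA", "DE", "DOS", "DO", "DAS"]

SHARED_SURNAME_PROB = 0.9
ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def draw_name(sex: str, rng: np.random.Generator) -> tuple[str, str]:
    """Draw a (full name, mother's full name) pair.

    Small pools are intentional: collisions in full names occur at a rate
    comparable to a real state registry, which is what makes fuzzy
    deduplication and linkage nontrivial.
    """
    given = MALE_GIVEN if sex == "male" else FEMALE_GIVEN
    first = given[rng.integers(len(given))]
    n_sur = 1 + int(rng.random() < 0.7)
    surnames = [SURNAMES[rng.integers(len(SURNAMES))] for _ in range(n_sur)]
    tokens = [first]
    if rng.random() < 0.45:  # middle given name
        tokens.append(given[rng.integers(len(given))])
    for i, s in enumerate(surnames):
        if rng.random() < 0.35:
            tokens.append(CONNECTIVES[rng.integers(len(CONNECTIVES))])
        tokens.append(s)
    name = " ".join(tokens)

    m_first = FEMALE_GIVEN[rng.integers(len(FEMALE_GIVEN))]
    if rng.random() < SHARED_SURNAME_PROB:
        m_sur = surnames[rng.integers(len(surnames))]
    else:
        m_sur = SURNAMES[rng.integers(len(SURNAMES))]
    m_tokens = [m_first]
    if rng.random() < 0.35:
        m_tokens.append(CONNECTIVES[rng.integers(len(CONNECTIVES))])
    m_tokens.append(m_sur)
    return name, " ".join(m_tokens)


def perturb_string(name: str, noise: NameNoise, rng: np.random.Generator) -> str:
    """Corrupt a name string according to the configured noise model.

    Token-level errors first (drop a non-initial token, swap adjacent
    tokens), then independent per-character corruption events, each a
    substitution, deletion, or insertion with the configured weights.
    Deterministic for a fixed generator state.
    """
    if not name:
        raise ValueError("name must be nonempty")
    tokens = name.split()
    if len(tokens) > 1 and noise.token_drop_prob > 0 \
            and rng.random() < noise.token_drop_prob:
        drop = 1 + int(rng.integers(len(tokens) - 1))
        tokens = tokens[:drop] + tokens[drop + 1:]
    if len(tokens) > 1 and noise.token_swap_prob > 0 \
            and rng.random() < noise.token_swap_prob:
        i = int(rng.integers(len(tokens) - 1))
        tokens[i], tokens[i + 1] = tokens[i + 1], tokens[i]
    s = " ".join(tokens)
    if noise.char_error_prob <= 0:
        return s
    w = np.array([noise.sub_weight, noise.del_weight, noise.ins_weight])
    w = w / w.sum()
    out: list[str] = []
    for ch in s:
        if rng.random() >= noise.char_error_prob:
            out.append(ch)
            continue
        op = rng.choice(3, p=w)
        if op == 0:  # substitute with a different letter
            repl = ch
            while repl == ch:
                repl = ALPHABET[rng.integers(26)]
            out.append(repl)
        elif op == 1:  # delete
            continue
        else:  # insert before
            out.append(ALPHABET[rng.integers(26)])
            out.append(ch)
    return "".join(out)
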