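"""Brute-force reference implementations used by several test modules.

Deliberately written with different machinery (Counter multisets, explicit
product loops) from the package's own decomposition logic, so agreement is
meaningful.
"""

from collections import Counter
from itertools import product

from pgdhla.family import InformativityClass


def transmitted_options(embryo, parent_pair, other_pair):
    """All alleles `parent` could have transmitted to produce `embryo`."""
    opts = set()
    for p, m in product(parent_pair, other_pair):
        if Counter((p, m)) == Counter(embryo):
            opts.add(p)
    return opts


def oracle_sides(father_pair, mother_pair):
    """(paternal informative, maternal informative) by exhaustive enumeration."""
    pat = len(set(father_pair)) == 2
    mat = len(set(mother_pair)) == 2
    for p, m in product(set(father_pair), set(mother_pair)):
        embryo = (p, m)
        if len(transmitted_options(embryo, father_pair, mother_pair)) != 1:
            pat = False
        if len(transmitted_options(embryo, mother_pair, father_pair)) != 1:
            mat = False
    return pat, mat


def oracle_class(father_pair, mother_pair):
    pat, mat = oracle_sides(father_pair, mother_pair)
    if pat and mat:
        return InformativityClass.FULLY_INFORMATIVE
    if pat:
        return InformativityClass.PATERNAL_ONLY
    if mat:
        return InformativityClass.MATERNAL_ONLY
    return InformativityClass.UNINFORMATIVE
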