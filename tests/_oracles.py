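"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the production code paths: the run scanner enumerates
maximal runs positionally over a raw permutation, and the closure oracle uses
networkx reachability over a graph parsed separately from the package's
ontology machinery.
"""

from __future__ import annotations

import io

import networkx as nx
import obonet

from syntenykit.genome_model import GeneFeature
from syntenykit.synteny_blocks import OrthologPair


def maximal_runs(seq: list[int]) -> list[tuple[int, int, int]]:
    """All maximal sequential runs in a permutation, as (start, end, direction).

    A run is a set of consecutive positions whose successive value deltas are
    all +1 or all -1; it is maximal when it cannot be extended on either side.
    Singleton positions not inside any longer run are singleton runs
    (direction 0). For distinct values the maximal runs partition positions.
    """
    n = len(seq)
    runs: list[tuple[int, int, int]] = []
    covered = [False] * n
    for i in range(n):
        for d in (1, -1):
            j = i
            while j + 1 < n and seq[j + 1] - seq[j] == d:
                j += 1
            if j == i:
                continue
            left_extendable = i > 0 and seq[i] - seq[i - 1] == d
            if not left_extendable:
                runs.append((i, j, d))
                for k in range(i, j + 1):
                    covered[k] = True
    for i in range(n):
        if not covered[i]:
            runs.append((i, i, 0))
    runs.sort()
    return runs


def permutation_features(perm: list[int], ref_taxon: int = 90001, comp_taxon: int = 90002):
    """Build a single-chromosome genome pair whose comparison gene order is `perm`.

    Reference gene i sits at position i; its ortholog sits at position perm[i]
    in the comparison genome, so the comparison-ordinal sequence scanned in
    reference order is exactly perm (1-based).
    """
    n = len(perm)
    ref = [
        GeneFeature(f"a{i:03d}", f"a{i}", ref_taxon, "1", 1000 + i * 100, 1000 + i * 100 + 50)
        for i in range(n)
    ]
    comp = [
        GeneFeature(f"b{i:03d}", f"b{i}", comp_taxon, "1",
                    1000 + perm[i] * 100, 1000 + perm[i] * 100 + 50)
        for i in range(n)
    ]
    pairs = [OrthologPair(f"a{i:03d}", f"b{i:03d}") for i in range(n)]
    return ref, comp, pairs


def blocks_by_oracle(perm: list[int], min_anchors: int) -> list[dict]:
    """Expected blocks for a permutation genome pair, from the run enumeration."""
    ref, comp, _ = permutation_features(perm)
    out = []
    for i, j, d in maximal_runs(perm):
        if j - i + 1 < min_anchors:
            continue
        refs = ref[i:j + 1]
        comps = [comp[k] for k in range(i, j + 1)]
        out.append(
            {
                "ref_span": (min(f.start for f in refs), max(f.end for f in refs)),
                "comp_span": (min(f.start for f in comps), max(f.end for f in comps)),
                "orientation": "-" if d == -1 else "+",
                "anchor_ids": tuple(f"a{k:03d}" for k in range(i, j + 1)),
            }
        )
    return out


def nx_descendant_closure(obo_text: str, term_id: str) -> frozenset[str]:
    """Closure oracle: networkx reachability over obonet's raw child->parent graph."""
    g = obonet.read_obo(io.StringIO(obo_text))
    restricted = nx.DiGraph()
    restricted.add_nodes_from(g.nodes)
    for child, parent, rel in g.edges(keys=True):
        if rel in ("is_a", "part_of"):
            restricted.add_edge(parent, child)   # parent -> child
    return frozenset(nx.descendants(restricted, term_id)) | {term_id}
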