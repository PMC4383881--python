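"""Indirect protease-substrate connection through the protease web.

A classic relay: MMP2 cleaves (inactivates) the inhibitor SERPING1, which
inhibits the protease C1S, which cleaves complement C4.  Observing a C4
neo-terminus in an MMP2 perturbation experiment is therefore explainable
without any direct MMP2 -> C4 cleavage.  The path search finds the
cleave -> inhibit -> cleave chain and emits it as Graphviz DOT.
"""

from termikit import (
    CleavageEvent,
    InhibitionEvent,
    Knowledgebase,
    PathQuery,
    PathTarget,
    Protein,
    build_web,
    extend_with_query,
    find_paths,
    to_dot,
)

seq = "ACDEFGHIKLMNPQRSTVWY" * 10
kb = Knowledgebase(
    proteins=[Protein(a, a, "human", seq)
              for a in ("MMP2", "SERPING1", "C1S", "C4")],
    cleavages=[CleavageEvent("MMP2", "SERPING1", 50, "assay", "human"),
               CleavageEvent("C1S", "C4", 80, "assay", "human")],
    inhibitions=[InhibitionEvent("SERPING1", "C1S", "assay")],
)

query = PathQuery("MMP2", (PathTarget("C4", position=81, terminus_type="N"),))
web = extend_with_query(build_web(kb, species="human"), query)
result = find_paths(web, query)

for path in result.explanations["C4"]:
    kinds = "/".join(e.kind for e in path.edges)
    print(f"explanation ({kinds}): {' -> '.join(path.nodes)}")
for path in result.hypothesized_direct["C4"]:
    print(f"hypothesized direct: {' -> '.join(path.nodes)} "
          "(no knowledgebase support)")

print("\nDOT output (solid = knowledgebase edge, dotted = hypothesized,"
      " tee = inhibition):")
print(to_dot(result.all_paths(), web, query_protease="MMP2",
             list_proteins=["C4"]))
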