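"""Base-case cost-effectiveness of mesh hernia repair versus no treatment.

Runs the 10-year Markov cohort model for 707,121 Ghanaian men aged 50 with
a symptomatic inguinal hernia, once with everyone repaired (by a medical
doctor or a surgeon) and once untreated, then compares discounted costs and
DALYs.  The ICER is the extra spend per DALY averted; anything below
Ghana's USD 371-491 threshold band counts as cost-effective.
"""

from herniacea import (
    ModelParameters,
    against_threshold,
    base_case_life_table,
    run_cea,
)

params = ModelParameters()
life_table = base_case_life_table()

for provider in ("md", "surgeon"):
    res = run_cea(params, life_table, provider)
    verdict = against_threshold(res, 371.0, 491.0)
    print(f"--- repair by {provider} vs no treatment ---")
    print(f"  total cost            USD {res.cost_intervention / 1e6:10.2f} million")
    print(f"  total DALYs (treated)     {res.daly_intervention:12,.2f}")
    print(f"  total DALYs (untreated)   {res.daly_comparator:12,.2f}")
    print(f"  DALYs averted             {res.incremental_dalys_averted:12,.2f}")
    print(f"  ICER                  USD {res.icer:10.2f} per DALY averted")
    print(f"  per patient: cost USD {res.cost_per_person_intervention:.2f}, "
          f"DALYs averted {res.dalys_averted_per_person:.3f}")
    print(f"  against USD 371-491 threshold: {verdict}")
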