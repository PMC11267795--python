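# Pathway definitions consumed by function_summary.pathway_completeness.
# Steps are the enzymatic stages of the pathway; the key gene (when given)
# is tracked separately from the steps and is required for any completeness
# flag.  Hydrogenotrophic methanogenesis is modelled as eight steps with
# methyl-coenzyme M reductase (mcr) as the key gene.
methanogenesis:
  steps: [step1, step2, step3, step4, step5, step6, step7, step8]
  key_gene: mcr
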