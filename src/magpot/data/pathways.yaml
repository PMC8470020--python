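# Default essential-gene sets (KEGG orthology identifiers) for the seven
# recognised CO2-fixation pathways. Curated working sets, editable by the
# user; `key` genes are the diagnostic enzymes, `guard` genes (roTCA only)
# must all be present before an autotrophy call is accepted regardless of
# the completeness threshold.
pathways:
  CBB:
    description: Calvin-Benson-Bassham reductive pentose phosphate cycle
    essential: [K01601, K01602, K00855, K00927, K00134, K01623, K00615, K01086]
    key: [K01601, K00855]            # RuBisCO large subunit; phosphoribulokinase
  WL:
    description: reductive acetyl-CoA (Wood-Ljungdahl) pathway
    essential: [K00198, K14138, K00194, K00197, K01938, K01491, K00297, K15023]
    key: [K00198, K14138]            # CO dehydrogenase; acetyl-CoA synthase
  rTCA:
    description: reductive tricarboxylic acid cycle
    essential: [K15230, K15231, K00174, K00175, K01902, K01903, K00239, K01679, K00024, K01595]
    key: [K15230, K15231]            # ATP-citrate lyase subunits
  3-HP:
    description: 3-hydroxypropionate bicycle
    essential: [K02160, K01961, K01962, K01963, K14468, K14469, K08691, K14449, K14470, K09709]
    key: [K14468, K14469]            # malonyl-CoA reductase; propionyl-CoA synthase
  3-HP/4-HB:
    description: 3-hydroxypropionate/4-hydroxybutyrate cycle
    essential: [K01964, K15037, K15036, K15017, K15039, K15018, K15019, K15020, K14466, K18602]
    key: [K14466]                    # 4-hydroxybutyryl-CoA dehydratase
  DC/4-HB:
    description: dicarboxylate/4-hydroxybutyrate cycle
    essential: [K00169, K00170, K00171, K00172, K01006, K15038, K14465, K14467, K14534, K14466]
    key: [K15038, K14466]
  roTCA:
    description: reversed oxidative tricarboxylic acid cycle
    essential: [K01647, K01681, K00031, K00174, K00175, K01902, K01903, K00239, K00240, K01679, K00024]
    key: [K01647]                    # citrate synthase
    guard: [K01681, K00031, K00174, K00175, K01902, K01903, K00239, K00240, K01679, K00024]
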