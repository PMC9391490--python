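taxon,specimen_id,element,position_label,stage,functional_lines,functional_is_minimum,replacement_lines,estimated_replacement_lines,printed_rate_days,rate_method,rate_is_minimum,expected_discrepancy,note
Mesenosaurus,ROMVP 85502,dentary,fam1,,,False,,,39,direct,False,False,per-family line counts not reported; rate reported directly
Mesenosaurus,ROMVP 85443,maxilla,fam1,,,False,,,34,direct,False,False,left maxilla TR sections; rate reported directly
Mesenosaurus,ROMVP 85457,maxilla,mx10,,,False,,,46,direct,False,False,rate reported directly
Mesenosaurus,ROMVP 85457,maxilla,mx12,,,False,,,36,direct,False,False,rate reported directly
Mesenosaurus,ROMVP 85457,maxilla,mx15,,,False,,,35,direct,False,False,rate reported directly
Dimetrodon,ROMVP 85510,maxilla,mx-fam,,459,False,354,,105,direct,False,False,functional and replacement line counts both measured
Haptodus,Hap-UTM-001,maxilla,mx-fam,,152,False,,,152,minimum,True,False,no replacement tooth and no resorption pit; rate is a lower bound
Watongia,holotype,maxilla,mx19,,81,True,,,,,True,False,resorption pit present; crown apex missing so age is a minimum
Watongia,holotype,maxilla,mx19-adjacent,,68,True,,,,,True,False,adjacent tooth not under replacement; crown apex missing
Watongia,holotype,maxilla,mx18,,145,False,,,,,False,False,second tooth with a resorption pit
Watongia,holotype,maxilla,ll-tooth,,108,False,,,,,False,False,complete tooth with no resorption pit; LL section
Oromycter,ROMVP 85516,maxilla,mx07,,506,False,,115,391,rp_height,False,True,estimate attributed to the mx09 family in the text but the arithmetic uses the 506-line mx07 tooth
Oromycter,ROMVP 85516,maxilla,mx09,,426,False,,,,,False,False,tooth without a resorption pit
Ennatosaurus,PIN 4542,dentary,d07,,567,False,,136,431,rp_height,False,False,smaller resorption pit; replacement estimated from RP height
Ennatosaurus,PIN 4542,dentary,d08,,628,False,,169,459,rp_height,False,False,larger resorption pit; replacement estimated from RP height
Edaphosaurus,USNM PAL 706602,maxilla,mx09,,506,False,,131,381,rp_height,False,True,reported rate 381 inconsistent with reported counts (506-131=375)
Edaphosaurus,USNM PAL 706602,maxilla,mx10,,429,False,,,,,False,False,tooth without a resorption pit
Delorhynchus,ROMVP 85513,maxilla,fam1,,147,False,43,,104,direct,False,False,functional and replacement line counts both measured
Colobomycter,ROMVP 85521,premaxilla,pmx-fam,,157,False,59,,98,direct,False,False,functional and replacement line counts both measured
Captorhinus,ROMVP 85525,premaxilla,pmx-fam,,146,False,69,,77,direct,False,False,functional and replacement line counts both measured
Opisthodontosaurus,ROMVP 85511,dentary,d04,,151,False,,,,,False,False,maximum tooth age only
Opisthodontosaurus,ROMVP 85511,dentary,d05,,155,False,,,,,False,False,maximum tooth age only
Opisthodontosaurus,ROMVP 85511,dentary,d06,,206,False,,,182,rp_height,False,False,rate estimated from resorption-pit height; replacement line count not reported
Opisthodontosaurus,ROMVP 85511,dentary,d07,,258,False,,,193,rp_height,False,False,rate estimated from resorption-pit height; replacement line count not reported
Seymouria,ROMVP 85515,dentary,fam1,,171,False,,36,135,rp_height,False,False,replacement estimated from RP height at 36 lines
Varanus_bengalensis,ROM R271,maxilla,mx04,,188,False,,,110,dentine_extent,False,False,replacement record not continuous; rate from dentine extent over mean line width
Varanus_komodoensis,adult-1,dentary,isolated-1,attachment,106,False,,,,,False,False,isolated tooth in the process of attachment; not yet ankylosed
Varanus_komodoensis,adult-1,dentary,isolated-2,attachment,135,False,,,,,False,False,isolated tooth in the process of attachment; not yet ankylosed
Varanus_komodoensis,zoo-shed,dentary,shed-1,shed,227,False,,,,,False,False,isolated shed tooth
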