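name,impact,cost,needs,standards,evidence,priority,expertise,notes
NICE diagnostic questions,Limited,Low,High prevalence,"No, not meeting minimum standards.",No supporting evidence.,Local priority.,"Yes, there is local expertise.",Screening questions for postnatal depression
Guided self help,Moderate,Low,High prevalence,"No, not meeting minimum standards.",Moderate supporting evidence.,Both local and national priority.,"Yes, there is local expertise.",
Computerised CBT,Limited,Low,High prevalence,"No, not meeting minimum standards.",Moderate supporting evidence.,Both local and national priority.,"Yes, there is local expertise.",
Exercise,Limited,Moderate,High prevalence,"No, not meeting minimum standards.",Limited supporting evidence.,Local priority.,"Yes, there is local expertise.",
Health visitor listening visits,Moderate,Moderate,High prevalence,"No, not meeting minimum standards.",Moderate supporting evidence.,Both local and national priority.,"Yes, there is local expertise.",
Practice counsellor referral,Moderate,High,High prevalence,"No, not meeting minimum standards.",Moderate supporting evidence.,Both local and national priority.,"Yes, there is local expertise.",
Brief CBT,Limited,Moderate,High prevalence,"No, not meeting minimum standards.",Limited supporting evidence.,Both local and national priority.,"Yes, there is local expertise.",
Full CBT,Moderate,High,High prevalence,"No, not meeting minimum standards.",Limited supporting evidence.,Both local and national priority.,"Yes, there is local expertise.",
Anti-depressants,Limited,Low,High prevalence,"No, not meeting minimum standards.",Limited supporting evidence.,Local priority.,"Yes, there is local expertise.",
Anti-depressants and psychological therapies together,Limited,Low,High prevalence,"No, not meeting minimum standards.",Moderate supporting evidence.,Local priority.,"Yes, there is local expertise.",
EPDS diagnostic tool,Moderate,Low,High prevalence,"No, not meeting minimum standards.",Limited supporting evidence.,Local priority.,"Yes, there is local expertise.",
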