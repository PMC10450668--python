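case_id,correct_text,specialty,chief_complaint
sleep1,Obstructive sleep apnea,pulmonology,daytime sleepiness
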