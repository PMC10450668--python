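case_id,user_id,rank,diagnosis_text,tenure
sleep1,user1,1,sleep apnea,resident
sleep1,user1,2,obstructive sleep apnea,resident
sleep1,user1,3,narcolepsy,resident
sleep1,user1,4,circadian rhythm sleep disorder,resident
sleep1,user2,1,OSA—obstructive sleep apnea,attending physician
sleep1,user3,1,Narcolepsy,medical student
sleep1,user3,2,Insomnia,medical student
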