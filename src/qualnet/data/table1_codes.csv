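theme_id,code_id,label,patient_count,expert_count
1,1.1,(Concerns about) informed consents,0,5
1,1.2,Concerns about ethics approvals,0,4
1,1.3,Ethical concerns,0,2
1,1.4,Views on/Concerns about ethics committees,0,3
1,1.5,(Issues w.r.t.) studies with ethics approvals,0,4
1,1.6,(Concerns about the) importance of ethics,0,3
1,1.7,Ethical issues,0,6
2,2.1,Views on health technology assessment (HTA),0,1
2,2.2,(Concerns about) liquid biopsies,0,2
2,2.3,Ethics and economics,0,1
2,2.4,Cost concerns,0,3
2,2.5,Views on health economics,1,6
2,2.6,(Concerns about the) role of pharmaceutical industry,0,5
2,2.7,Health economic concerns,0,7
2,2.8,Lobbying,0,2
2,2.9,(Concerns about) private versus public,1,2
3,3.1,(Concerns about) preclinical studies,2,2
3,3.2,Translational issues,0,6
3,3.3,(Concerns about) knowledge gap,0,7
3,3.4,Views on evidence,0,8
3,3.5,Views on/Concerns about randomized controlled trials (RCTs),0,10
4,4.1,Views on hype,0,6
4,4.2,Various understandings of PM,1,8
4,4.3,Examples of personalized treatment,0,6
4,4.4,Overdiagnosis,0,8
5,5.1,Views on/Concerns about genetic screening w.r.t. the public,1,3
5,5.2,(Concerns w.r.t.) the Austrian context,2,7
5,5.3,(Concerns about) access limitation to treatment,2,4
5,5.4,Public health,1,3
5,5.5,(Concerns about the) importance of preventive medicine,1,3
6,6.1,Views on/Concerns about progress in cancer research,1,5
6,6.2,Improving understanding in society,0,3
6,6.3,(Concerns about) data storage,0,2
6,6.4,(Concerns about) big data collection and use,2,7
6,6.5,(Concerns about) consent for data collection,2,5
7,7.1,Expertise (assessment),1,1
7,7.2,Decision-making patients' perspective,2,0
7,7.3,Concerns about patients' participation in the decision-making process,0,6
7,7.4,Shared decision-making,0,5
7,7.5,(Concerns about) communication,0,8
7,7.6,(Concerns about the) importance of doctor-patient relationships,0,4
7,7.7,(Concerns about) incidental findings,1,5
7,7.8,(Concerns about) best decision-making,0,11
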